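"""Detection of gene-inactivating mutations in codon-aware alignments.

Four lesion classes are scanned: frameshift indels, premature stop codons,
splice-site dinucleotide disruptions (GT donor / AG acceptor), and diagnostic
key-residue missense changes such as the Schiff's base counterion replacement
E113G in a short-wave cone opsin.

Indel polarity is assigned against the intact reference taxon: a gap in the
focal taxon where the reference has sequence is a deletion; sequence in the
focal taxon where the reference is gapped is an insertion.  Adjacent but
non-contiguous gap runs are never merged, even if jointly in-frame; each run
is evaluated on its own, which mirrors per-row reporting of lesion tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .data_io import (
    AMBIGUITY,
    CodonAlignment,
    GeneModel,
    STOP_CODONS,
    reference_codon_columns,
    translate_codon,
)

logger = logging.getLogger("opsinphylo")

LESION_TYPES = (
    "frameshift_deletion",
    "frameshift_insertion",
    "premature_stop",
    "splice_donor",
    "splice_acceptor",
    "key_residue_missense",
)


@dataclass
class LesionRecord:
    """One inactivating mutation, possibly shared by several taxa."""

    lesion_type: str
    gene: str
    segment: str
    start: int  # 1-based alignment column
    end: int    # inclusive
    taxa: list[str]
    detail: str = ""
    polymorphic: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.lesion_type}")
        if self.start > self.end:
            raise ValueError("lesion start > end")
        if self.lesion_type in ("splice_donor", "splice_acceptor") and \
                self.end - self.start != 1:
            raise ValueError("splice lesions span exactly one dinucleotide")

    def key(self) -> tuple:
        return (self.lesion_type, self.segment, self.start, self.end, self.detail)


@dataclass(frozen=True)
class KeyResidueRule:
    """Critical residue whose replacement abolishes protein function."""

    gene: str
    reference_residue_number: int
    intact_states: frozenset[str]
    inactivating_states: frozenset[str]
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.intact_states & self.inactivating_states:
            raise ValueError("intact and inactivating residue sets must be disjoint")

    @classmethod
    def from_dict(cls, d: dict) -> "KeyResidueRule":
        return cls(
            gene=d["gene"],
            reference_residue_number=int(d["residue"]),
            intact_states=frozenset(d["intact"]),
            inactivating_states=frozenset(d["inactivating"]),
            rationale=d.get("rationale", ""),
        )


def _segment_name(model: GeneModel) -> dict[tuple[int, int], str]:
    names: dict[tuple[int, int], str] = {}
    counts = {"exon": 0, "intron": 0}
    for seg in model.segments:
        counts[seg.kind] += 1
        names[(seg.start, seg.end)] = f"{seg.kind}{counts[seg.kind]}"
    return names


def _segment_of(model: GeneModel, col: int) -> str:
    for (start, end), name in _segment_name(model).items():
        if start <= col <= end:
            return name
    return "?"


def _merge(records: list[LesionRecord]) -> list[LesionRecord]:
    """Merge records identical in type/coordinates/detail into one multi-taxon row."""
    merged: dict[tuple, LesionRecord] = {}
    for rec in records:
        k = rec.key()
        if k in merged:
            merged[k].taxa.extend(rec.taxa)
            merged[k].polymorphic.update(rec.polymorphic)
        else:
            merged[k] = rec
    out = list(merged.values())
    out.sort(key=lambda r: (r.start, r.end, r.lesion_type))
    return out


# ---------------------------------------------------------------------------
# frameshift indels
# ---------------------------------------------------------------------------

def scan_indels(
    aln: CodonAlignment,
    model: GeneModel,
    polymorphic_taxa: dict[str, set[tuple[int, int]]] | None = None,
) -> list[LesionRecord]:
    """Frameshift indels within exons, relative to the reference-defined frame.

    A maximal run of columns in which the focal taxon is gapped and the
    reference is not (deletion), or vice versa (insertion), yields a record
    when the affected length is not a multiple of 3.  Taxa sharing identical
    coordinates are merged into one record.
    """
    polymorphic_taxa = polymorphic_taxa or {}
    ref_label = model.reference_taxon
    ref = aln[ref_label]
    exon_cols = [c for c in model.exon_columns() if c >= model.frame_anchor]
    records: list[LesionRecord] = []

    for taxon in aln.taxa:
        if taxon == ref_label:
            continue
        row = aln[taxon]
        for sign in ("deletion", "insertion"):
            run: list[int] = []

            def flush(run: list[int]) -> None:
                if not run:
                    return
                length = len(run)
                if length % 3 == 0:
                    return
                start, end = run[0], run[-1]
                poly = (start, end) in polymorphic_taxa.get(taxon, set())
                records.append(LesionRecord(
                    lesion_type=f"frameshift_{sign}",
                    gene=model.gene_name,
                    segment=_segment_of(model, start),
                    start=start,
                    end=end,
                    taxa=[taxon],
                    detail=f"{length}-bp frameshift {sign}",
                    polymorphic={taxon: poly},
                ))

            prev_col: int | None = None
            for col in exon_cols:
                t, r = row[col - 1], ref[col - 1]
                hit = (t == "-" and r != "-") if sign == "deletion" \
                    else (t != "-" and r == "-")
                contiguous = prev_col is not None and col == prev_col + 1
                if hit:
                    if run and not contiguous:
                        flush(run)
                        run = []
                    run.append(col)
                else:
                    flush(run)
                    run = []
                prev_col = col
            flush(run)

    return _merge(records)


# ---------------------------------------------------------------------------
# premature stop codons
# ---------------------------------------------------------------------------

def scan_premature_stops(aln: CodonAlignment, model: GeneModel) -> list[LesionRecord]:
    """First in-frame premature stop per taxon, in the taxon's own frame.

    Each taxon's exon sequence is gap-stripped and read in consecutive
    triplets from the frame anchor, so upstream frameshift indels shift the
    frame in which downstream stops are sought (the reading a ribosome would
    attempt).  Only stops strictly upstream of the reference taxon's terminal
    stop are reported; codons containing ambiguity codes are skipped and
    logged.  Stops caused solely by alignment gaps cannot occur because
    codons are formed from the taxon's own bases.
    """
    ref_label = model.reference_taxon
    exon_cols = [c for c in model.exon_columns() if c >= model.frame_anchor]
    ref_codons = reference_codon_columns(aln, model)
    # column of the first base of the reference terminal stop (or +inf if the
    # reference CDS carries no stop)
    ref = aln[ref_label]
    ref_stop_col = float("inf")
    if ref_codons:
        last = ref_codons[-1]
        codon = "".join(ref[c - 1] for c in last)
        if codon in STOP_CODONS:
            ref_stop_col = last[0]

    records: list[LesionRecord] = []
    for taxon in aln.taxa:
        if taxon == ref_label:
            continue
        row = aln[taxon]
        bases = [(c, row[c - 1]) for c in exon_cols if row[c - 1] != "-"]
        for i in range(0, len(bases) - 2, 3):
            triple = bases[i:i + 3]
            codon = "".join(b for _, b in triple)
            if any(b not in "ACGT" for b in codon):
                logger.info("%s/%s: skipping untranslatable codon %s at column %d",
                            model.gene_name, taxon, codon, triple[0][0])
                continue
            if codon in STOP_CODONS:
                start = triple[0][0]
                if start >= ref_stop_col:
                    break  # at/after the reference stop: not premature
                records.append(LesionRecord(
                    lesion_type="premature_stop",
                    gene=model.gene_name,
                    segment=_segment_of(model, start),
                    start=start,
                    end=triple[2][0],
                    taxa=[taxon],
                    detail=f"premature {codon}",
                    polymorphic={taxon: False},
                ))
                break  # only the first stop per taxon

    return _merge(records)


# ---------------------------------------------------------------------------
# splice sites
# ---------------------------------------------------------------------------

def scan_splice_sites(aln: CodonAlignment, model: GeneModel) -> list[LesionRecord]:
    """Canonical GT/AG check at every intron boundary, per taxon.

    The donor is the taxon's first two intron bases, the acceptor its last
    two (skipping alignment gaps); introns fully deleted in a taxon are
    unassessable and logged.
    """
    records: list[LesionRecord] = []
    names = _segment_name(model)
    for seg in model.intron_segments:
        seg_name = names[(seg.start, seg.end)]
        for taxon in aln.taxa:
            row = aln[taxon]
            bases = [(c, row[c - 1]) for c in seg.columns if row[c - 1] != "-"]
            if len(bases) < 4:
                logger.info("%s/%s: %s unassessable (deleted)",
                            model.gene_name, taxon, seg_name)
                continue
            donor_cols, donor = zip(*bases[:2])
            acc_cols, acceptor = zip(*bases[-2:])
            donor_s, acceptor_s = "".join(donor), "".join(acceptor)
            if donor_s != "GT" and all(b in "ACGT" for b in donor_s):
                records.append(LesionRecord(
                    lesion_type="splice_donor",
                    gene=model.gene_name,
                    segment=seg_name,
                    start=donor_cols[0],
                    end=donor_cols[1],
                    taxa=[taxon],
                    detail=f"GT to {donor_s}",
                    polymorphic={taxon: False},
                ))
            if acceptor_s != "AG" and all(b in "ACGT" for b in acceptor_s):
                records.append(LesionRecord(
                    lesion_type="splice_acceptor",
                    gene=model.gene_name,
                    segment=seg_name,
                    start=acc_cols[0],
                    end=acc_cols[1],
                    taxa=[taxon],
                    detail=f"AG to {acceptor_s}",
                    polymorphic={taxon: False},
                ))
    return _merge(records)


# ---------------------------------------------------------------------------
# key residues
# ---------------------------------------------------------------------------

def scan_key_residues(
    aln: CodonAlignment,
    model: GeneModel,
    rules: list[KeyResidueRule],
) -> list[LesionRecord]:
    """Diagnostic missense lesions at critical residues.

    Each rule names a reference residue number (through the gene model's
    numbering map); taxa whose translated residue at the mapped codon falls
    in the rule's inactivating set yield one merged record.
    """
    records: list[LesionRecord] = []
    codon_cols = reference_codon_columns(aln, model)
    for rule in rules:
        if not rule.inactivating_states:
            continue
        codon_idx = model.residue_to_codon(rule.reference_residue_number)
        cols = codon_cols[codon_idx - 1]
        intact = sorted(rule.intact_states)
        for taxon in aln.taxa:
            if taxon == model.reference_taxon:
                continue
            row = aln[taxon]
            codon = "".join(row[c - 1] for c in cols)
            if "-" in codon:
                logger.info("%s/%s: residue %d deleted, unassessable",
                            model.gene_name, taxon, rule.reference_residue_number)
                continue
            if any(b not in AMBIGUITY or len(AMBIGUITY[b]) > 1 for b in codon):
                logger.info("%s/%s: residue %d ambiguous, unassessable",
                            model.gene_name, taxon, rule.reference_residue_number)
                continue
            aa = translate_codon(codon)
            if aa in rule.inactivating_states:
                records.append(LesionRecord(
                    lesion_type="key_residue_missense",
                    gene=model.gene_name,
                    segment=_segment_of(model, cols[0]),
                    start=cols[0],
                    end=cols[2],
                    taxa=[taxon],
                    detail=f"{intact[0] if intact else '?'}"
                           f"{rule.reference_residue_number}{aa}",
                    polymorphic={taxon: False},
                ))
    return _merge(records)


def scan_all(
    aln: CodonAlignment,
    model: GeneModel,
    rules: list[KeyResidueRule] | None = None,
    polymorphic_taxa: dict[str, set[tuple[int, int]]] | None = None,
) -> list[LesionRecord]:
    """Run the four scanners and return the combined, coordinate-sorted catalogue."""
    records = scan_indels(aln, model, polymorphic_taxa)
    records += scan_premature_stops(aln, model)
    records += scan_splice_sites(aln, model)
    if rules:
        records += scan_key_residues(aln, model, rules)
    records.sort(key=lambda r: (r.start, r.end, r.lesion_type))
    return records
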