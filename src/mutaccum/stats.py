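"""Treatment-level mutation statistics.

Mutation frequency (events per reference site, optionally per
generation), the six-class folded substitution spectrum with Ti/Tv
ratios and chi-squared comparisons, deletion-size distributions,
homozygous/heterozygous ratios, fold changes, gene-impact counting
against GFF3 gene models, and sequence-context annotation of indels
(homopolymer runs, microhomology, tandem-repeat units).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import chi2_contingency

from .exceptions import ParameterDomainError

logger = logging.getLogger(__name__)

# complementary substitutions merged: the six canonical classes, keyed by
# the pyrimidine-strand change they fold to
SUBSTITUTION_CLASSES = (
    "G:C>A:T",  # transition
    "A:T>G:C",  # transition
    "G:C>T:A",
    "G:C>C:G",
    "A:T>T:A",
    "A:T>C:G",
)
TRANSITION_CLASSES = ("G:C>A:T", "A:T>G:C")

_FOLD = {
    ("C", "T"): "G:C>A:T", ("G", "A"): "G:C>A:T",
    ("T", "C"): "A:T>G:C", ("A", "G"): "A:T>G:C",
    ("C", "A"): "G:C>T:A", ("G", "T"): "G:C>T:A",
    ("C", "G"): "G:C>C:G", ("G", "C"): "G:C>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
}

DEFAULT_DELETION_BINS = ((1, 1), (2, 10), (11, 50), (51, None))


def fold_substitution(ref: str, alt: str) -> str:
    """Merged class of a single-base substitution (strand-folded)."""
    key = (ref.upper(), alt.upper())
    if key not in _FOLD:
        raise ParameterDomainError(f"not an ACGT substitution: {ref}>{alt}")
    return _FOLD[key]


@dataclass
class SpectrumSummary:
    """Counts over the six merged substitution classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )

    @property
    def ti_count(self) -> int:
        return sum(self.counts[c] for c in TRANSITION_CLASSES)

    @property
    def tv_count(self) -> int:
        return sum(
            self.counts[c] for c in SUBSTITUTION_CLASSES
            if c not in TRANSITION_CLASSES
        )

    @property
    def total(self) -> int:
        return self.ti_count + self.tv_count

    def proportions(self) -> dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.counts.items()}


@dataclass(frozen=True)
class MFSummary:
    """Mutation frequency: events per reference site (and per generation)."""

    n_events: int
    genome_length: int
    generations: int = 1
    mf: float = field(init=False)
    mf_per_generation: float = field(init=False)

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ParameterDomainError("genome_length must be > 0")
        if self.generations < 1:
            raise ParameterDomainError("generations must be >= 1")
        object.__setattr__(self, "mf", self.n_events / self.genome_length)
        object.__setattr__(self, "mf_per_generation", self.mf / self.generations)


def mutation_frequency(
    n_events: int, genome_length: int, generations: int = 1
) -> MFSummary:
    """Events divided by reference length; optionally per generation."""
    return MFSummary(n_events=n_events, genome_length=genome_length,
                     generations=generations)


def _iter_sbs(events) -> Iterable[tuple[str, str]]:
    """Yield (ref, alt) for SBS events from a DataFrame or event objects."""
    if isinstance(events, pd.DataFrame):
        sub = events[events["category"] == "SBS"]
        yield from zip(sub["ref"], sub["alt"])
    else:
        for e in events:
            if e.category == "SBS":
                yield e.ref, e.alt


def substitution_spectrum(events) -> SpectrumSummary:
    """Fold SBS events into the six merged substitution classes.

    Non-ACGT alleles are rejected per event (logged), never fatal.
    """
    spectrum = SpectrumSummary()
    for ref, alt in _iter_sbs(events):
        try:
            spectrum.counts[fold_substitution(ref, alt)] += 1
        except ParameterDomainError as exc:
            logger.warning("spectrum: skipped event (%s)", exc)
    return spectrum


def titv_ratio(spectrum: SpectrumSummary) -> float:
    """Transition/transversion ratio.

    Returns ``inf`` when there are transitions but no transversions and
    ``nan`` when the spectrum is empty.
    """
    ti, tv = spectrum.ti_count, spectrum.tv_count
    if ti == 0 and tv == 0:
        return math.nan
    if tv == 0:
        return math.inf
    return ti / tv


def titv_chisq(
    spectrum_a: SpectrumSummary, spectrum_b: SpectrumSummary
) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) comparing two
    Ti/Tv compositions on the 2x2 table [ti, tv] x [a, b]."""
    table = np.array(
        [[spectrum_a.ti_count, spectrum_a.tv_count],
         [spectrum_b.ti_count, spectrum_b.tv_count]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterDomainError("chi-squared undefined: zero margin in table")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class DeletionSizeDistribution:
    bins: tuple
    counts: dict[str, int]
    proportions: dict[str, float]
    fraction_ge2: float
    n: int


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def deletion_size_distribution(
    events, bins: tuple = DEFAULT_DELETION_BINS, include_sv_dels: bool = False
) -> DeletionSizeDistribution | None:
    """Binned deletion-size proportions and the fraction of deletions >= 2 bp.

    Operates on Del1/DelGE2 events (plus SV deletions when requested).
    Returns None on empty input rather than a NaN-filled distribution.
    """
    if isinstance(events, pd.DataFrame):
        mask = events["category"].isin(["Del1", "DelGE2"])
        sizes = list(events.loc[mask, "size"])
        if include_sv_dels:
            sv = events[(events["category"] == "SV") & (events["size"] > 0)
                        & (events["alt"].astype(str).str.contains("DEL"))]
            sizes += list(sv["size"])
    else:
        sizes = [e.size for e in events if e.category in ("Del1", "DelGE2")]
        if include_sv_dels:
            sizes += [
                e.size for e in events
                if e.category == "SV" and e.size > 0 and "DEL" in str(e.alt)
            ]
    if not sizes:
        return None
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    counts = dict.fromkeys(labels, 0)
    for s in sizes:
        for (lo, hi), label in zip(bins, labels):
            if s >= lo and (hi is None or s <= hi):
                counts[label] += 1
                break
    n = len(sizes)
    return DeletionSizeDistribution(
        bins=bins,
        counts=counts,
        proportions={k: v / n for k, v in counts.items()},
        fraction_ge2=sum(1 for s in sizes if s >= 2) / n,
        n=n,
    )


def homo_het_ratio(events) -> float:
    """Homozygous/heterozygous event-count ratio (inf on zero het, nan empty)."""
    if isinstance(events, pd.DataFrame):
        n_homo = int((events["zygosity"] == "homozygous").sum())
        n_het = int((events["zygosity"] == "heterozygous").sum())
    else:
        n_homo = sum(1 for e in events if e.zygosity == "homozygous")
        n_het = sum(1 for e in events if e.zygosity == "heterozygous")
    if n_homo == 0 and n_het == 0:
        return math.nan
    if n_het == 0:
        return math.inf
    return n_homo / n_het


def fold_change(value_a: float, value_b: float) -> float:
    """value_a / value_b; the routine fold statement of the analysis."""
    if value_b <= 0:
        raise ParameterDomainError("fold change needs a positive denominator")
    return value_a / value_b


# ---------------------------------------------------------------------------
# gene impact

@dataclass
class GeneImpact:
    gene_ids: list[str]
    n_genes_affected: int
    affects_amino_acid: bool


def load_gene_models(gff_path: str | Path) -> gffutils.FeatureDB:
    """Load a GFF3 of gene/mRNA/CDS features into an in-memory database."""
    return gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def load_reference(fasta_path: str | Path) -> dict[str, str]:
    """Reference sequences as plain upper-case strings keyed by contig."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def genome_length_from_fasta(fasta_path: str | Path) -> int:
    """Reference length = sum of contig lengths of the supplied FASTA."""
    return sum(len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta"))


def _codon_change(
    chrom_seq: str, cds, pos: int, ref: str, alt: str
) -> bool | None:
    """Whether an SBS at ``pos`` changes the encoded amino acid.

    Returns None when the codon cannot be resolved (triggers the
    interval-overlap fallback in the caller).
    """
    if cds.strand == "+":
        idx = pos - cds.start  # 0-based offset into the coding sequence
    elif cds.strand == "-":
        idx = cds.end - pos
    else:
        return None
    if idx < 0:
        return None
    codon_index = idx // 3
    within = idx % 3
    if cds.strand == "+":
        c_start = cds.start + 3 * codon_index  # 1-based genomic
        codon = chrom_seq[c_start - 1 : c_start + 2]
        if len(codon) < 3:
            return None
        mutated = codon[:within] + alt + codon[within + 1 :]
        if codon[within] != ref:
            return None
    else:
        c_end = cds.end - 3 * codon_index
        genomic = chrom_seq[c_end - 3 : c_end]
        if len(genomic) < 3:
            return None
        codon = str(Seq(genomic).reverse_complement())
        alt_rc = str(Seq(alt).reverse_complement())
        ref_rc = str(Seq(ref).reverse_complement())
        if codon[within] != ref_rc:
            return None
        mutated = codon[:within] + alt_rc + codon[within + 1 :]
    return str(Seq(codon).translate()) != str(Seq(mutated).translate())


def affected_genes(
    event,
    gene_db: gffutils.FeatureDB,
    reference: Mapping[str, str] | None = None,
) -> GeneImpact:
    """Genes overlapped by an event span and whether amino acids change.

    ``event`` may be a MutationEvent or a mapping/Series with sample,
    chrom, start, end, category, ref, alt fields.  Any indel, complex or
    SV intersecting a CDS is taken to affect the protein; an SBS in a CDS
    is checked by codon translation against the reference (falling back
    to plain CDS overlap, logged, when the codon cannot be resolved).
    """
    get = (lambda k: event[k]) if not hasattr(event, "chrom") else (
        lambda k: getattr(event, k)
    )
    chrom, start, end = get("chrom"), int(get("start")), int(get("end"))
    category = get("category")

    genes = list(
        gene_db.region(seqid=chrom, start=start, end=end, featuretype="gene")
    )
    gene_ids = sorted(g.id for g in genes)
    cds_hits = list(
        gene_db.region(seqid=chrom, start=start, end=end, featuretype="CDS")
    )
    affects = False
    if cds_hits:
        if category == "SBS":
            if reference is None or chrom not in reference:
                logger.warning("no reference for codon check at %s:%d; "
                               "falling back to CDS overlap", chrom, start)
                affects = True
            else:
                ref, alt = str(get("ref")), str(get("alt"))
                verdicts = [
                    _codon_change(reference[chrom], cds, start, ref, alt)
                    for cds in cds_hits
                ]
                if any(v is None for v in verdicts):
                    logger.warning("unresolvable codon at %s:%d; "
                                   "falling back to CDS overlap", chrom, start)
                    affects = True
                else:
                    affects = any(verdicts)
        else:
            affects = True
    return GeneImpact(
        gene_ids=gene_ids,
        n_genes_affected=len(gene_ids),
        affects_amino_acid=affects,
    )


# ---------------------------------------------------------------------------
# sequence context

@dataclass
class ContextAnnotation:
    """Sequence context of an indel.

    homopolymer_run: length of the reference homopolymer run containing
    (deletions) or adjacent to (insertions) a 1-bp indel, else 0.
    microhomology: longest identical stretch shared between a >= 2 bp
    deletion and its flanks (max of prefix-vs-3' flank and
    suffix-vs-5' flank).  tandem_repeat_unit: the deleted segment exactly
    repeats in the adjacent flank.  truncated: the window hit a contig
    edge.
    """

    homopolymer_run: int = 0
    microhomology: int = 0
    tandem_repeat_unit: bool = False
    truncated: bool = False
    homopolymer_threshold: int = 3
    microhomology_threshold: int = 2

    @property
    def homopolymer_associated(self) -> bool:
        return self.homopolymer_run >= self.homopolymer_threshold

    @property
    def microhomology_associated(self) -> bool:
        return self.microhomology >= self.microhomology_threshold


def _run_length(seq: str, idx0: int) -> int:
    """Length of the homopolymer run in ``seq`` containing 0-based ``idx0``."""
    base = seq[idx0]
    left = idx0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = idx0
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def context_annotate(
    event,
    reference: Mapping[str, str],
    homopolymer_threshold: int = 3,
    microhomology_threshold: int = 2,
) -> ContextAnnotation:
    """Annotate an indel event with its local sequence context.

    1-bp indels: length of the homopolymer run at/adjacent to the site.
    Deletions >= 2 bp: microhomology between the deleted segment and its
    flanks, and whether the deletion removes one unit of a tandem repeat.
    """
    get = (lambda k: event[k]) if not hasattr(event, "chrom") else (
        lambda k: getattr(event, k)
    )
    chrom = get("chrom")
    start, end = int(get("start")), int(get("end"))
    category, size = get("category"), int(get("size"))
    seq = reference[chrom]
    ann = ContextAnnotation(
        homopolymer_threshold=homopolymer_threshold,
        microhomology_threshold=microhomology_threshold,
    )

    if category in ("Del1", "Ins1"):
        if category == "Del1":
            ann.homopolymer_run = _run_length(seq, start - 1)
        else:
            # inserted base; run in the reference adjacent to the anchor
            inserted = str(get("alt"))[-1]
            run = 0
            i = start  # 0-based index of the base after the anchor
            while i < len(seq) and seq[i] == inserted:
                run += 1
                i += 1
            i = start - 1
            while i >= 0 and seq[i] == inserted:
                run += 1
                i -= 1
            ann.homopolymer_run = run
        if start <= 1 or end >= len(seq):
            ann.truncated = True
        return ann

    if category in ("DelGE2", "SV") and size >= 2:
        deleted = seq[start - 1 : end]
        window = len(deleted)
        flank5 = seq[max(0, start - 1 - window) : start - 1]
        flank3 = seq[end : end + window]
        if len(flank5) < window or len(flank3) < window:
            ann.truncated = True
        mh = max(
            _common_prefix(deleted, flank3),
            _common_prefix(deleted[::-1], flank5[::-1]),
        )
        ann.microhomology = mh
        ann.tandem_repeat_unit = deleted == flank3 or deleted == flank5
        return ann

    return ann


# ---------------------------------------------------------------------------
# treatment summaries

@dataclass
class TreatmentSummary:
    treatment: str
    n_samples: int
    n_events: int
    n_homozygous: int
    n_heterozygous: int
    mf: MFSummary
    spectrum: SpectrumSummary
    titv: float
    homo_het: float
    deletion_sizes: DeletionSizeDistribution | None
    category_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "n_samples": self.n_samples,
            "n_events": self.n_events,
            "n_homozygous": self.n_homozygous,
            "n_heterozygous": self.n_heterozygous,
            "mf": self.mf.mf,
            "mf_per_generation": self.mf.mf_per_generation,
            "titv": self.titv,
            "homo_het_ratio": self.homo_het,
            "fraction_deletions_ge2": (
                self.deletion_sizes.fraction_ge2 if self.deletion_sizes else None
            ),
            "spectrum": dict(self.spectrum.counts),
            "category_counts": dict(self.category_counts),
        }


def summarize_treatments(
    events: pd.DataFrame,
    sample_meta: Mapping[str, Mapping],
    genome_length: int,
    zygosity: str | None = "homozygous",
) -> dict[str, TreatmentSummary]:
    """Aggregate per-treatment statistics from an event table.

    ``sample_meta`` maps sample name -> {"treatment": ..., "generations":
    ...}.  MF, spectrum, Ti/Tv, deletion sizes and category counts are
    computed on events of the requested ``zygosity`` (the heritable
    homozygous fraction by default; pass None for all events); the
    homo/het ratio always uses all events.
    """
    summaries: dict[str, TreatmentSummary] = {}
    treatments: dict[str, list[str]] = {}
    for sample, meta in sample_meta.items():
        treatments.setdefault(str(meta["treatment"]), []).append(sample)
    for treatment, samples in treatments.items():
        sub_all = events[events["sample"].isin(samples)]
        sub = sub_all if zygosity is None else sub_all[
            sub_all["zygosity"] == zygosity
        ]
        generations = max(
            int(sample_meta[s].get("generations", 1)) for s in samples
        )
        # MF is per sample: events per genome per plant, averaged over plants
        n_events = len(sub)
        mf = MFSummary(
            n_events=n_events,
            genome_length=genome_length * len(samples),
            generations=generations,
        )
        spectrum = substitution_spectrum(sub)
        summaries[treatment] = TreatmentSummary(
            treatment=treatment,
            n_samples=len(samples),
            n_events=n_events,
            n_homozygous=int((sub_all["zygosity"] == "homozygous").sum()),
            n_heterozygous=int((sub_all["zygosity"] == "heterozygous").sum()),
            mf=mf,
            spectrum=spectrum,
            titv=titv_ratio(spectrum),
            homo_het=homo_het_ratio(sub_all),
            deletion_sizes=deletion_size_distribution(sub),
            category_counts=sub["category"].value_counts().to_dict(),
        )
    return summaries
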