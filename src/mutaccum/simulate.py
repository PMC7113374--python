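"""Synthetic cohort generator for the mutation-characterization pipeline.

Produces a random reference (FASTA), optional gene models (GFF3 with
embedded ATG..stop ORFs), per-sample truth mutation tables, and per-sample
VCFs whose records carry AD/AF genotype fields with the statistical
structure the downstream filters assume:

* per-treatment mutation profiles (category mix, folded substitution
  spectrum, deletion-size distribution, SV rate);
* bimodal allele-frequency draws — a tight peak near 1.0 for homozygous
  and a broad symmetric peak near 0.5 for heterozygous mutations;
* shared background artifact sites injected into several samples;
* spurious low-AF noise calls;
* Mendelian selfing transmission over the accumulation design (one
  selfing for M2-style acute arms; five inductions with 1..5 selfings
  for M6 accumulation arms), via the :mod:`~mutaccum.inheritance` model.

Treatment presets name the experimental arms (control, gamma-1000,
gamma-1500, carbon-125-175, chronic-500mGy, chronic-100mGy); their
percentage vectors are editable data, transcribed from the reported
ranges, and their induced mutation rates are back-calculated from the
observed homozygous mutation frequencies through the transmission model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import inheritance
from .calls import EVENT_COLUMNS, ORIGIN_INDEL, ORIGIN_SMALL, ORIGIN_SV
from .exceptions import ParameterDomainError
from .stats import SUBSTITUTION_CLASSES

__all__ = [
    "MutationProfile",
    "NoiseModel",
    "TruthCall",
    "TruthEvent",
    "SimulatedCohort",
    "generate_reference",
    "generate_gene_models",
    "sample_truth_mutations",
    "emit_cohort_vcfs",
    "simulate_cohort",
    "compare_to_truth",
    "get_preset",
    "PRESET_NAMES",
]

_CLASS_TO_ALT = {
    "G:C>A:T": {"G": "A", "C": "T"},
    "A:T>G:C": {"A": "G", "T": "C"},
    "G:C>T:A": {"G": "T", "C": "A"},
    "G:C>C:G": {"G": "C", "C": "G"},
    "A:T>T:A": {"A": "T", "T": "A"},
    "A:T>C:G": {"A": "C", "T": "G"},
}

CATEGORY_ORDER = ("SBS", "Del1", "DelGE2", "Ins1", "InsGE2", "Complex", "SV")


@dataclass
class MutationProfile:
    """Generating distributions for one treatment arm.

    ``mf_per_site`` is the *induced heterozygous* mutation rate per site
    per irradiated generation; the observed homozygous MF follows from it
    through the Mendelian transmission design.  ``deletion_size_dist``
    gives bin probabilities for deletions >= 2 bp (the 1-bp share is the
    Del1 category weight).
    """

    name: str
    mf_per_site: float
    category_mix: dict[str, float]
    spectrum: dict[str, float]
    deletion_size_dist: Sequence[tuple[tuple[int, int], float]] = (
        ((2, 10), 1.0),
    )
    insertion_size_range: tuple[int, int] = (2, 8)
    sv_types: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.5, "INV": 0.25, "DUP": 0.15, "TRA": 0.1}
    )
    sv_size_range: tuple[int, int] = (300, 3000)

    def __post_init__(self):
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ParameterDomainError("category_mix must sum to 1")
        if abs(sum(self.spectrum.values()) - 1.0) > 1e-9:
            raise ParameterDomainError("spectrum must sum to 1")
        unknown = set(self.spectrum) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ParameterDomainError(f"unknown spectrum classes: {unknown}")

    @property
    def titv(self) -> float:
        ti = self.spectrum.get("G:C>A:T", 0) + self.spectrum.get("A:T>G:C", 0)
        return ti / (1.0 - ti)


@dataclass
class NoiseModel:
    """AF noise and artifact structure of the emitted VCFs.

    Homozygous/heterozygous AFs are Beta draws (defaults: Beta(97,3),
    mean 0.97, and Beta(50,50), mean 0.5).  ``background_sites`` shared
    artifact sites are injected into >= ``background_share_min`` samples
    each; ``spurious_low_af_per_sample`` is the Poisson mean of AF < 0.25
    noise records per sample.
    """

    homo_af_beta: tuple[float, float] = (97.0, 3.0)
    het_af_beta: tuple[float, float] = (50.0, 50.0)
    background_sites: int = 5
    background_share_min: int = 3
    spurious_low_af_per_sample: float = 10.0
    depth_mean: float = 40.0

    def draw_af(self, zygosity: str, rng: np.random.Generator) -> float:
        a, b = self.homo_af_beta if zygosity == "homozygous" else self.het_af_beta
        return float(rng.beta(a, b))


NO_NOISE = NoiseModel(background_sites=0, spurious_low_af_per_sample=0.0)


@dataclass
class TruthCall:
    """One caller-level record backing a truth event."""

    pos: int
    ref: str
    alt: str
    origin: str
    sv_type: str | None = None
    sv_end: int | None = None


@dataclass
class TruthEvent:
    sample: str
    chrom: str
    start: int
    end: int
    category: str
    zygosity: str
    size: int
    members: list[TruthCall]

    def to_row(self) -> dict:
        return {
            "sample": self.sample, "chrom": self.chrom,
            "start": self.start, "end": self.end,
            "category": self.category, "zygosity": self.zygosity,
            "size": self.size, "members": len(self.members),
            "ref": ",".join(m.ref for m in self.members),
            "alt": ",".join(m.alt for m in self.members),
        }


# ---------------------------------------------------------------------------
# reference and gene models

def generate_reference(
    length: int,
    gc: float = 0.36,
    n_contigs: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random reference sequence(s) with the requested GC content."""
    if not 0.0 < gc < 1.0:
        raise ParameterDomainError(f"gc must be in (0,1), got {gc}")
    if length < n_contigs:
        raise ParameterDomainError("length must cover all contigs")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = length // n_contigs
    reference = {}
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)
        reference[f"chr{i + 1}"] = seq.tobytes().decode()
    return reference


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_STOP_CODONS = ("TAA", "TAG", "TGA")


def _random_orf(length: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop; ``length`` a multiple of 3."""
    n_body = length // 3 - 2
    codons = ["ATG"]
    bases = "ACGT"
    for _ in range(n_body):
        while True:
            codon = "".join(rng.choice(list(bases)) for _ in range(3))
            if codon not in _STOP_CODONS:
                break
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def generate_gene_models(
    reference: dict[str, str],
    n_genes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gene_length: int = 900,
    min_spacing: int = 150,
    within: tuple[str, int, int] | None = None,
) -> tuple[list[dict], dict[str, str]]:
    """Place non-overlapping single-exon protein-coding genes.

    Each gene gets an ATG..stop ORF written into the returned (modified)
    reference, on a random strand.  ``within`` restricts placement to a
    (chrom, start, end) window.  Returns (genes, modified reference);
    gene dicts carry chrom/start/end/strand/id.  Raises on infeasible
    packing.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if gene_length % 3:
        raise ParameterDomainError("gene_length must be a multiple of 3")
    seqs = {k: list(v) for k, v in reference.items()}
    if within is not None:
        regions = [(within[0], within[1], within[2])]
    else:
        regions = [(c, 1, len(s)) for c, s in reference.items()]
    capacity = sum(
        (end - start + 1) // (gene_length + min_spacing) for _, start, end in regions
    )
    if n_genes > capacity:
        raise ParameterDomainError(
            f"cannot pack {n_genes} genes of {gene_length} bp into the region(s)"
        )
    genes: list[dict] = []
    # deal slots round-robin over regions, evenly spaced within each
    per_region = np.zeros(len(regions), dtype=int)
    for i in range(n_genes):
        per_region[i % len(regions)] += 1
    gi = 0
    for (chrom, rstart, rend), k in zip(regions, per_region):
        if k == 0:
            continue
        span = rend - rstart + 1
        slot = span // k
        if slot < gene_length + 2:
            raise ParameterDomainError("infeasible packing within region")
        for j in range(k):
            lo = rstart + j * slot
            hi = min(rend, lo + slot - 1) - gene_length
            start = int(rng.integers(lo, max(lo, hi) + 1))
            end = start + gene_length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            orf = _random_orf(gene_length, rng)
            if strand == "-":
                comp = str.maketrans("ACGT", "TGCA")
                orf = orf.translate(comp)[::-1]
            seqs[chrom][start - 1 : end] = list(orf)
            gi += 1
            genes.append(
                {"chrom": chrom, "start": start, "end": end,
                 "strand": strand, "id": f"gene{gi:04d}"}
            )
    return genes, {k: "".join(v) for k, v in seqs.items()}


def write_gff3(
    genes: Sequence[dict], reference: Mapping[str, str], path: str | Path
) -> None:
    """Write gene/mRNA/CDS features (one exon per gene) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in reference.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for g in sorted(genes, key=lambda g: (g["chrom"], g["start"])):
            c, s, e, st, gid = g["chrom"], g["start"], g["end"], g["strand"], g["id"]
            fh.write(f"{c}\tsim\tgene\t{s}\t{e}\t.\t{st}\t.\tID={gid}\n")
            fh.write(f"{c}\tsim\tmRNA\t{s}\t{e}\t.\t{st}\t.\t"
                     f"ID={gid}.1;Parent={gid}\n")
            fh.write(f"{c}\tsim\tCDS\t{s}\t{e}\t.\t{st}\t0\t"
                     f"ID={gid}.1.cds;Parent={gid}.1\n")


# ---------------------------------------------------------------------------
# truth mutations

class _Occupancy:
    """Blocked reference intervals, padded so independent events never
    fall within complex-merging distance of each other."""

    def __init__(self, pad: int = 12):
        self.pad = pad
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self._by_chrom.get(chrom, ()):
            if start <= e + self.pad and end >= s - self.pad:
                return False
        return True

    def block(self, chrom: str, start: int, end: int) -> None:
        self._by_chrom.setdefault(chrom, []).append((start, end))


def _draw_position(
    reference: dict[str, str], rng: np.random.Generator, margin: int = 60
) -> tuple[str, int]:
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
    pos = int(rng.integers(margin + 1, len(reference[c]) - margin))
    return c, pos


def _draw_zygosity(k: int, rng: np.random.Generator) -> str | None:
    """Realized state after k selfings: homozygous/heterozygous/None (lost)."""
    z = inheritance.zygosity_probabilities(k)
    u = rng.random()
    if u < z.p_homo:
        return "homozygous"
    if u < z.p_homo + z.p_het:
        return "heterozygous"
    return None


def _sample_one_event(
    sample: str,
    profile: MutationProfile,
    reference: dict[str, str],
    zygosity: str,
    rng: np.random.Generator,
    occupied: _Occupancy,
    max_tries: int = 200,
) -> TruthEvent | None:
    categories = list(profile.category_mix)
    weights = np.array([profile.category_mix[c] for c in categories])
    category = categories[int(rng.choice(len(categories), p=weights))]

    for _ in range(max_tries):
        chrom, pos = _draw_position(reference, rng)
        seq = reference[chrom]
        if category == "SBS":
            classes = list(profile.spectrum)
            cls = classes[int(rng.choice(
                len(classes), p=np.array([profile.spectrum[c] for c in classes])
            ))]
            base = seq[pos - 1]
            if base not in _CLASS_TO_ALT[cls]:
                continue
            call = TruthCall(pos=pos, ref=base, alt=_CLASS_TO_ALT[cls][base],
                             origin=ORIGIN_SMALL)
            start = end = pos
            size = 0
            members = [call]
        elif category in ("Del1", "DelGE2"):
            if category == "Del1":
                size = 1
            else:
                bins = list(profile.deletion_size_dist)
                probs = np.array([p for _, p in bins])
                lo, hi = bins[int(rng.choice(len(bins), p=probs / probs.sum()))][0]
                size = int(rng.integers(lo, hi + 1))
            if pos + size >= len(seq):
                continue
            ref = seq[pos - 1 : pos + size]
            origin = ORIGIN_SMALL if size <= 10 else ORIGIN_INDEL
            call = TruthCall(pos=pos, ref=ref, alt=ref[0], origin=origin)
            start, end = pos + 1, pos + size
            members = [call]
        elif category in ("Ins1", "InsGE2"):
            if category == "Ins1":
                size = 1
            else:
                size = int(rng.integers(*profile.insertion_size_range))
            inserted = "".join(rng.choice(list("ACGT")) for _ in range(size))
            base = seq[pos - 1]
            call = TruthCall(pos=pos, ref=base, alt=base + inserted,
                             origin=ORIGIN_SMALL)
            start = end = pos
            members = [call]
        elif category == "Complex":
            n_members = 2 if rng.random() < 0.7 else 3
            members = []
            p = pos
            ok = True
            for _ in range(n_members):
                if p >= len(seq) - 1:
                    ok = False
                    break
                base = seq[p - 1]
                alt = rng.choice([b for b in "ACGT" if b != base])
                members.append(TruthCall(pos=p, ref=base, alt=str(alt),
                                         origin=ORIGIN_SMALL))
                p += int(rng.integers(2, 9))
            if not ok:
                continue
            start, end = members[0].pos, members[-1].pos
            size = end - start + 1
        else:  # SV
            types = list(profile.sv_types)
            sv_type = types[int(rng.choice(
                len(types), p=np.array([profile.sv_types[t] for t in types])
            ))]
            if sv_type == "TRA":
                size = 0
                sv_end = pos
            else:
                size = int(rng.integers(*profile.sv_size_range))
                sv_end = pos + size
                if sv_end >= len(seq):
                    continue
            call = TruthCall(pos=pos, ref=seq[pos - 1], alt=f"<{sv_type}>",
                             origin=ORIGIN_SV, sv_type=sv_type, sv_end=sv_end)
            start, end = pos, sv_end
            members = [call]

        if not occupied.is_free(chrom, start, end):
            continue
        occupied.block(chrom, start, end)
        return TruthEvent(sample=sample, chrom=chrom, start=start, end=end,
                          category=category, zygosity=zygosity, size=size,
                          members=members)
    return None


def sample_truth_mutations(
    profile: MutationProfile,
    reference: dict[str, str],
    design: inheritance.AccumulationDesign,
    sample: str,
    rng: np.random.Generator,
    occupied: _Occupancy | None = None,
) -> list[TruthEvent]:
    """Draw the surviving truth mutations for one plant.

    For each of the ``design.generations`` induction generations, a
    Poisson(mf_per_site x genome length) number of heterozygous events is
    induced; each is pushed through k = observe_at - g selfings of
    Mendelian transmission and kept with its realized zygosity (lost
    mutations are dropped).  Placement is uniform, collision-free and
    padded against accidental complex merging.
    """
    occupied = occupied if occupied is not None else _Occupancy()
    genome_length = sum(len(s) for s in reference.values())
    events: list[TruthEvent] = []
    for g in range(1, design.generations + 1):
        k = design.observe_at - g
        n_induced = rng.poisson(profile.mf_per_site * genome_length)
        for _ in range(n_induced):
            zyg = _draw_zygosity(k, rng)
            if zyg is None:
                continue
            ev = _sample_one_event(sample, profile, reference, zyg, rng, occupied)
            if ev is None:
                raise ParameterDomainError(
                    "could not place a mutation after bounded retries; "
                    "genome too small for the requested rate"
                )
            events.append(ev)
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return events


# ---------------------------------------------------------------------------
# VCF emission

def _vcf_header(reference: Mapping[str, str], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, seq in reference.items():
        header.add_line(f"##contig=<ID={chrom},length={len(seq)}>")
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,'
                    'Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                    'Description="Structural variant type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,'
                    'Description="Structural variant length">')
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                    'Description="Caller origin">')
    for t in ("DEL", "INS", "INV", "DUP", "TRA"):
        header.add_line(f'##ALT=<ID={t},Description="{t} structural variant">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,'
                    'Description="Mutant read fraction">')
    header.add_sample(sample)
    return header


@dataclass
class _VcfRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str
    af: float
    gt: tuple[int, int]
    sv_type: str | None = None
    sv_end: int | None = None


def _af_to_counts(
    af: float, rng: np.random.Generator, depth_mean: float, round_down: bool = False
) -> tuple[int, int]:
    depth = max(10, int(rng.poisson(depth_mean)))
    alt = int(np.floor(af * depth)) if round_down else int(round(af * depth))
    alt = min(max(alt, 0), depth)
    return depth - alt, alt


def _write_sample_vcf(
    path: str | Path,
    sample: str,
    records: list[_VcfRecord],
    reference: Mapping[str, str],
    rng: np.random.Generator,
    noise: NoiseModel,
) -> None:
    header = _vcf_header(reference, sample)
    chrom_order = {c: i for i, c in enumerate(reference)}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            symbolic = r.alt.startswith("<")
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt),
                qual=60, filter="PASS",
            )
            rec.info["ORIGIN"] = r.origin
            if symbolic:
                rec.info["SVTYPE"] = r.sv_type
                rec.info["SVLEN"] = r.sv_end - r.pos
                rec.stop = max(r.sv_end, r.pos)
            ref_n, alt_n = _af_to_counts(
                r.af, rng, noise.depth_mean, round_down=r.af <= 0.25
            )
            fmt = rec.samples[sample]
            fmt["GT"] = r.gt
            fmt["AD"] = (ref_n, alt_n)
            fmt["DP"] = ref_n + alt_n
            fmt["AF"] = alt_n / (ref_n + alt_n)
            out.write(rec)


def emit_cohort_vcfs(
    truth_by_sample: Mapping[str, list[TruthEvent]],
    noise: NoiseModel,
    reference: dict[str, str],
    outdir: str | Path,
    rng: np.random.Generator,
    occupied: _Occupancy | None = None,
) -> dict[str, list[tuple[str, str | None]]]:
    """Write one VCF per sample: truth records plus injected noise.

    Shared background artifact sites are injected with het-like AF into
    >= ``noise.background_share_min`` samples each; spurious low-AF
    (< 0.25) records are injected per sample.  Returns a mapping of
    sample -> [(vcf path, None)] consumable by the calls module.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    occupied = occupied if occupied is not None else _Occupancy()
    samples = list(truth_by_sample)
    per_sample: dict[str, list[_VcfRecord]] = {s: [] for s in samples}

    for sample, events in truth_by_sample.items():
        for ev in events:
            for m in ev.members:
                af = noise.draw_af(ev.zygosity, rng)
                gt = (1, 1) if ev.zygosity == "homozygous" else (0, 1)
                per_sample[sample].append(
                    _VcfRecord(chrom=ev.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                               origin=m.origin, af=af, gt=gt,
                               sv_type=m.sv_type, sv_end=m.sv_end)
                )

    # shared background artifact sites (small-variant origin, het-like AF)
    for _ in range(noise.background_sites):
        for _try in range(200):
            chrom, pos = _draw_position(reference, rng)
            if occupied.is_free(chrom, pos, pos):
                break
        occupied.block(chrom, pos, pos)
        base = reference[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        n_share = int(rng.integers(
            min(noise.background_share_min, len(samples)), len(samples) + 1
        ))
        chosen = rng.choice(samples, size=n_share, replace=False)
        for s in chosen:
            per_sample[str(s)].append(
                _VcfRecord(chrom=chrom, pos=pos, ref=base, alt=alt,
                           origin=ORIGIN_SMALL,
                           af=float(rng.uniform(0.40, 0.60)), gt=(0, 1))
            )

    # spurious low-AF noise
    for sample in samples:
        for _ in range(rng.poisson(noise.spurious_low_af_per_sample)):
            for _try in range(200):
                chrom, pos = _draw_position(reference, rng)
                if occupied.is_free(chrom, pos, pos):
                    break
            occupied.block(chrom, pos, pos)
            base = reference[chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            per_sample[sample].append(
                _VcfRecord(chrom=chrom, pos=pos, ref=base, alt=alt,
                           origin=ORIGIN_SMALL,
                           af=float(rng.uniform(0.05, 0.24)), gt=(0, 1))
            )

    vcfs: dict[str, list[tuple[str, str | None]]] = {}
    for sample in samples:
        path = outdir / f"{sample}.vcf"
        _write_sample_vcf(path, sample, per_sample[sample], reference, rng, noise)
        vcfs[sample] = [(str(path), None)]
    return vcfs


# ---------------------------------------------------------------------------
# presets

def _m2_design(mu: float) -> inheritance.AccumulationDesign:
    return inheritance.AccumulationDesign(
        generations=1, mutations_per_generation=mu
    )


def _m6_design(mu: float) -> inheritance.AccumulationDesign:
    return inheritance.AccumulationDesign(
        generations=5, mutations_per_generation=mu
    )


def induced_rate_for_observed_homo_mf(
    mf_homo_per_generation: float, design: inheritance.AccumulationDesign
) -> float:
    """Induced het rate per site per generation that yields the given
    observed homozygous MF per generation under the transmission design."""
    total_p_homo = sum(
        inheritance.zygosity_probabilities(design.observe_at - g).p_homo
        for g in range(1, design.generations + 1)
    )
    return mf_homo_per_generation * design.generations / total_p_homo


@dataclass(frozen=True)
class Preset:
    profile: MutationProfile
    design: inheritance.AccumulationDesign
    observed_homo_mf_per_generation: float
    description: str


def _build_presets() -> dict[str, Preset]:
    presets: dict[str, Preset] = {}

    def add(name, mf_obs, generations, mix, spectrum, del_dist, desc):
        design = (_m6_design if generations == 5 else _m2_design)(1.0)
        profile = MutationProfile(
            name=name,
            mf_per_site=induced_rate_for_observed_homo_mf(mf_obs, design),
            category_mix=mix,
            spectrum=spectrum,
            deletion_size_dist=del_dist,
        )
        presets[name] = Preset(profile=profile, design=design,
                               observed_homo_mf_per_generation=mf_obs,
                               description=desc)

    spectrum_control = {"G:C>A:T": 0.60, "A:T>G:C": 0.15, "G:C>T:A": 0.10,
                        "G:C>C:G": 0.05, "A:T>T:A": 0.05, "A:T>C:G": 0.05}
    spectrum_gamma = {"G:C>A:T": 0.36, "A:T>G:C": 0.20, "G:C>T:A": 0.17,
                      "G:C>C:G": 0.08, "A:T>T:A": 0.10, "A:T>C:G": 0.09}
    spectrum_carbon = {"G:C>A:T": 0.25, "A:T>G:C": 0.125, "G:C>T:A": 0.25,
                       "G:C>C:G": 0.125, "A:T>T:A": 0.15, "A:T>C:G": 0.10}
    spectrum_chronic = {"G:C>A:T": 0.28, "A:T>G:C": 0.15, "G:C>T:A": 0.22,
                        "G:C>C:G": 0.10, "A:T>T:A": 0.13, "A:T>C:G": 0.12}

    add("control", 11.1e-9, 5,
        {"SBS": 0.92, "Del1": 0.04, "DelGE2": 0.01, "Ins1": 0.02,
         "InsGE2": 0.01, "Complex": 0.0, "SV": 0.0},
        spectrum_control, (((2, 10), 1.0),),
        "unirradiated accumulation line; spontaneous mutations")
    add("gamma-1500", 2.2e-7, 1,
        {"SBS": 0.70, "Del1": 0.12, "DelGE2": 0.09, "Ins1": 0.05,
         "InsGE2": 0.02, "Complex": 0.02, "SV": 0.0},
        spectrum_gamma, (((2, 10), 0.92), ((11, 50), 0.08)),
        "acute gamma irradiation of dry seeds, 1500 Gy (75% of Dq)")
    add("gamma-1000", 1.4e-7, 1,
        {"SBS": 0.70, "Del1": 0.12, "DelGE2": 0.09, "Ins1": 0.05,
         "InsGE2": 0.02, "Complex": 0.02, "SV": 0.0},
        spectrum_gamma, (((2, 10), 0.92), ((11, 50), 0.08)),
        "acute gamma irradiation of dry seeds, 1000 Gy (50% of Dq)")
    add("carbon-125-175", 1.05e-7, 1,
        {"SBS": 0.345, "Del1": 0.11, "DelGE2": 0.36, "Ins1": 0.05,
         "InsGE2": 0.04, "Complex": 0.06, "SV": 0.035},
        spectrum_carbon,
        (((2, 10), 0.62), ((11, 50), 0.28), ((51, 99), 0.10)),
        "acute carbon-ion irradiation of dry seeds, 125/175 Gy merged")
    add("chronic-500mGy", 2.8e-7, 5,
        {"SBS": 0.65, "Del1": 0.10, "DelGE2": 0.13, "Ins1": 0.05,
         "InsGE2": 0.03, "Complex": 0.037, "SV": 0.003},
        spectrum_chronic,
        (((2, 10), 0.72), ((11, 50), 0.18), ((51, 99), 0.10)),
        "chronic gamma accumulation line, 500 mGy/h over 5 generations")
    add("chronic-100mGy", 4.6e-8, 5,
        {"SBS": 0.66, "Del1": 0.10, "DelGE2": 0.13, "Ins1": 0.05,
         "InsGE2": 0.03, "Complex": 0.03, "SV": 0.0},
        spectrum_chronic,
        (((2, 10), 0.72), ((11, 50), 0.18), ((51, 99), 0.10)),
        "chronic gamma accumulation line, 73-100 mGy/h over 5 generations")
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> Preset:
    if name not in _PRESETS:
        raise ParameterDomainError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        )
    return _PRESETS[name]


# ---------------------------------------------------------------------------
# cohort orchestration

@dataclass
class SimulatedCohort:
    outdir: Path
    samples: list[str]
    reference_path: Path
    gff_path: Path | None
    vcfs: dict[str, list[tuple[str, str | None]]]
    truth: pd.DataFrame
    truth_events: dict[str, list[TruthEvent]]
    genome_length: int
    config_path: Path
    preset: str
    seed: int


def simulate_cohort(
    preset: str = "gamma-1500",
    n_samples: int = 8,
    genome_length: int = 1_000_000,
    n_contigs: int = 1,
    gc: float = 0.36,
    n_genes: int = 0,
    seed: int = 0,
    outdir: str | Path = "simulated-cohort",
    profile: MutationProfile | None = None,
    design: inheritance.AccumulationDesign | None = None,
    noise: NoiseModel | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort on disk.

    Writes ``reference.fa``, optionally ``genes.gff3``, one VCF per
    sample, ``truth.tsv`` (the generating event table in the pipeline's
    schema) and ``cohort.yaml`` (a ready-to-run pipeline config).  A
    single seed fans out into independent per-stage streams.
    """
    p = get_preset(preset)
    profile = profile if profile is not None else p.profile
    design = design if design is not None else p.design
    noise = noise if noise is not None else NoiseModel()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    streams = np.random.SeedSequence(seed).spawn(4)
    rng_ref, rng_genes, rng_truth, rng_emit = map(np.random.default_rng, streams)

    reference = generate_reference(genome_length, gc=gc, n_contigs=n_contigs,
                                   rng=rng_ref)
    gff_path = None
    genes: list[dict] = []
    if n_genes > 0:
        genes, reference = generate_gene_models(reference, n_genes, rng=rng_genes)
        gff_path = outdir / "genes.gff3"
        write_gff3(genes, reference, gff_path)
    ref_path = outdir / "reference.fa"
    write_fasta(reference, ref_path)

    samples = [f"S{i + 1}" for i in range(n_samples)]
    occupied = _Occupancy()
    truth_by_sample = {
        s: sample_truth_mutations(profile, reference, design, s, rng_truth,
                                  occupied)
        for s in samples
    }
    vcfs = emit_cohort_vcfs(truth_by_sample, noise, reference, outdir,
                            rng_emit, occupied)

    truth_rows = [ev.to_row() for s in samples for ev in truth_by_sample[s]]
    truth = pd.DataFrame(truth_rows, columns=EVENT_COLUMNS)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    config = {
        "reference": "reference.fa",
        "samples": [
            {"name": s, "treatment": preset, "generations": design.generations,
             "vcfs": [{"path": Path(path).name, "origin": origin}
                      for path, origin in vcfs[s]]}
            for s in samples
        ],
    }
    config_path = outdir / "cohort.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    return SimulatedCohort(
        outdir=outdir, samples=samples, reference_path=ref_path,
        gff_path=gff_path, vcfs=vcfs, truth=truth,
        truth_events=truth_by_sample,
        genome_length=sum(len(s) for s in reference.values()),
        config_path=config_path, preset=preset, seed=seed,
    )


def compare_to_truth(events: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Event-level recovery metrics of a pipeline run against the truth table.

    Events match on (sample, chrom, start, end, category, zygosity).
    ``sensitivity`` is matched/truth; ``false_event_rate`` is the share
    of recovered events with no truth counterpart.
    """
    key = ["sample", "chrom", "start", "end", "category", "zygosity"]
    t = set(map(tuple, truth[key].itertuples(index=False)))
    r = set(map(tuple, events[key].itertuples(index=False)))
    matched = len(t & r)
    return {
        "n_truth": len(t),
        "n_recovered": len(r),
        "n_matched": matched,
        "sensitivity": matched / len(t) if t else float("nan"),
        "false_event_rate": (len(r) - matched) / len(r) if r else 0.0,
    }
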