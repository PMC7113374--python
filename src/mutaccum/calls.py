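"""Post-calling pipeline: filtering, zygosity, complex merging, classification.

Candidate variants arrive per sample from three caller origins (a
small-variant caller, a long-indel scanner, a structural-variant scanner)
and are reduced to a table of *mutation events* through, in order:

1. background exclusion — small-variant sites called in too many cohort
   samples are shared artifacts, not induced mutations;
2. allele-frequency filtering — calls with AF <= 25% are discarded;
3. scanner-specific filters — indel-scanner calls of <= 10 bp are dropped
   (the small-variant caller owns that size range), and scanner calls
   present in more than one sample are dropped;
4. zygosity calling from the mutant-read fraction — homozygous at
   AF >= 80%, heterozygous at 25% < AF < 80%, and in either case only if
   every other sample shows AF < 5% at the site;
5. complex merging — two or more small mutations of the same zygosity
   separated by gaps of < 10 bases become a single complex event;
6. classification into the seven categories SBS, Del1, DelGE2, Ins1,
   InsGE2, Complex, SV.

Every filter returns (kept, rejected-with-reason) so the pipeline audit
can account for each input call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml

from .exceptions import ParameterDomainError, PipelineError, UnclassifiableEventError

logger = logging.getLogger(__name__)

ORIGIN_SMALL = "small-variant"
ORIGIN_INDEL = "indel-scanner"
ORIGIN_SV = "sv-scanner"
ORIGINS = (ORIGIN_SMALL, ORIGIN_INDEL, ORIGIN_SV)

CATEGORIES = ("SBS", "Del1", "DelGE2", "Ins1", "InsGE2", "Complex", "SV")
SV_TYPES = ("DEL", "INS", "INV", "DUP", "TRA")

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"

EVENT_COLUMNS = [
    "sample", "chrom", "start", "end", "category",
    "zygosity", "size", "members", "ref", "alt",
]


@dataclass
class CandidateCall:
    """One caller record at one site for one sample, with cohort AF context.

    ``af`` is the proportion of mutant reads at the site; ``cohort_af``
    maps every cohort sample that has any record at (chrom, pos) to its
    AF there (absent sample => 0, queried via :meth:`max_other_af`).
    """

    sample: str
    chrom: str
    pos: int  # 1-based, VCF-style anchored coordinate
    ref: str
    alt: str
    origin: str
    af: float | None = None
    depth: int | None = None
    cohort_af: dict[str, float] = field(default_factory=dict)
    sv_type: str | None = None
    sv_end: int | None = None
    zygosity: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ParameterDomainError(f"pos must be >= 1, got {self.pos}")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ParameterDomainError(f"af must be in [0,1], got {self.af}")
        if self.origin not in ORIGINS:
            raise ParameterDomainError(f"unknown origin {self.origin!r}")
        if self.origin == ORIGIN_SMALL and self.ref == self.alt:
            raise ParameterDomainError("ref == alt for a small variant")

    @property
    def is_symbolic(self) -> bool:
        return self.alt.startswith("<")

    @property
    def variant_length(self) -> int:
        """Length of the sequence change: 0 for an SBS, indel size otherwise."""
        if self.is_symbolic:
            if self.sv_end is not None and self.sv_type in {"DEL", "INV", "DUP"}:
                return self.sv_end - self.pos
            return 0
        return abs(len(self.ref) - len(self.alt))

    @property
    def start(self) -> int:
        """1-based inclusive start of the affected reference span."""
        if self.is_symbolic:
            return self.pos
        if len(self.ref) > len(self.alt):  # deletion: anchor base not affected
            return self.pos + len(self.alt)
        return self.pos

    @property
    def end(self) -> int:
        """1-based inclusive end of the affected reference span."""
        if self.is_symbolic:
            return self.sv_end if self.sv_end is not None else self.pos
        return self.pos + len(self.ref) - 1

    def max_other_af(self) -> float:
        return max(
            (af for s, af in self.cohort_af.items() if s != self.sample),
            default=0.0,
        )


@dataclass
class MutationEvent:
    """Unit of mutation counting after merging and classification."""

    sample: str
    chrom: str
    start: int
    end: int
    category: str
    zygosity: str
    size: int
    members: list[CandidateCall]
    ref: str
    alt: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise UnclassifiableEventError(f"unknown category {self.category!r}")
        if self.category == "Complex" and len(self.members) < 2:
            raise UnclassifiableEventError("Complex event needs >= 2 members")
        zygs = {m.zygosity for m in self.members}
        samples = {m.sample for m in self.members}
        if len(zygs) > 1 or len(samples) > 1:
            raise UnclassifiableEventError(
                "event members must share one sample and one zygosity"
            )

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class Thresholds:
    """Filter thresholds; defaults follow the published pipeline."""

    af_min_exclusive: float = 0.25   # AF <= this is excluded
    af_homo_min: float = 0.80        # AF >= this is homozygous
    af_other_max: float = 0.05       # other samples must be below this
    background_share_min: int = 3    # "more than two independent samples"
    complex_gap: int = 10            # member gap strictly below this merges
    complex_min_members: int = 2
    scanner_min_len: int = 11        # indel-scanner calls below this dropped
    sv_min_len: int = 100            # linear indels at/above this are SVs

    def __post_init__(self):
        for name in ("af_min_exclusive", "af_homo_min", "af_other_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterDomainError(f"{name} must be in (0,1), got {v}")
        if self.complex_gap <= 0:
            raise ParameterDomainError("complex_gap must be > 0")


@dataclass
class SampleConfig:
    name: str
    vcfs: list[tuple[str, str | None]]  # (path, origin tag or None => INFO/ORIGIN)
    treatment: str = "unknown"
    dose_gy: float | None = None
    dose_rate: str | None = None
    generations: int = 1


@dataclass
class CohortConfig:
    samples: list[SampleConfig]
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        samples = []
        for s in raw["samples"]:
            vcfs = []
            for v in s["vcfs"]:
                if isinstance(v, str):
                    vcfs.append((str(base / v), None))
                else:
                    vcfs.append((str(base / v["path"]), v.get("origin")))
            samples.append(
                SampleConfig(
                    name=str(s["name"]),
                    vcfs=vcfs,
                    treatment=str(s.get("treatment", "unknown")),
                    dose_gy=s.get("dose_gy"),
                    dose_rate=s.get("dose_rate"),
                    generations=int(s.get("generations", 1)),
                )
            )
        thresholds = Thresholds(**raw.get("thresholds", {}))
        ref = raw.get("reference")
        if ref is not None:
            ref = str(base / ref)
        return cls(samples=samples, thresholds=thresholds, reference=ref)


# ---------------------------------------------------------------------------
# loading

def _record_af(rec, sample_idx: int, alt_idx: int) -> tuple[float | None, int | None]:
    """AF and depth for one alt of one sample; AD preferred, AF fallback."""
    fmt = rec.samples[sample_idx]
    ad = fmt.get("AD")
    if ad is not None and len(ad) > alt_idx + 1 and ad[0] is not None:
        total = sum(x for x in ad if x is not None)
        if total > 0:
            return ad[alt_idx + 1] / total, total
        return None, None
    af = fmt.get("AF")
    if af is not None:
        if isinstance(af, (tuple, list)):
            af = af[alt_idx] if len(af) > alt_idx else af[0]
        dp = fmt.get("DP")
        return float(af), int(dp) if dp is not None else None
    return None, None


def load_candidates(
    vcfs_by_sample: Mapping[str, Sequence[tuple[str, str | None]]],
) -> tuple[list[CandidateCall], list[dict]]:
    """Load per-sample candidate calls from VCFs and populate cohort AFs.

    ``vcfs_by_sample`` maps sample name -> [(path, origin)]; a ``None``
    origin means the record-level INFO/ORIGIN tag is used.  Multi-allelic
    records are split into one call per alt.  Records from which no AF
    can be derived are rejected (except symbolic SV records, which may
    legitimately lack read support counts).

    Returns (calls, rejected) where ``rejected`` lists dicts with a
    ``reason`` key.
    """
    calls: list[CandidateCall] = []
    rejected: list[dict] = []
    for sample, files in vcfs_by_sample.items():
        for path, origin_tag in files:
            with pysam.VariantFile(str(path)) as vf:
                names = list(vf.header.samples)
                sample_idx = names.index(sample) if sample in names else 0
                for rec in vf:
                    origin = origin_tag or rec.info.get("ORIGIN")
                    if origin not in ORIGINS:
                        rejected.append(
                            {"sample": sample, "chrom": rec.chrom, "pos": rec.pos,
                             "reason": f"unknown-origin:{origin}"}
                        )
                        continue
                    alts = rec.alts or ()
                    for alt_idx, alt in enumerate(alts):
                        af, depth = _record_af(rec, sample_idx, alt_idx)
                        symbolic = alt.startswith("<")
                        if af is None and not symbolic:
                            rejected.append(
                                {"sample": sample, "chrom": rec.chrom, "pos": rec.pos,
                                 "reason": "no-af"}
                            )
                            continue
                        sv_type = rec.info.get("SVTYPE")
                        sv_end = rec.stop if symbolic else None
                        calls.append(
                            CandidateCall(
                                sample=sample, chrom=rec.chrom, pos=rec.pos,
                                ref=rec.ref, alt=alt, origin=origin,
                                af=af, depth=depth,
                                sv_type=sv_type, sv_end=sv_end,
                            )
                        )
    attach_cohort_af(calls)
    return calls, rejected


def attach_cohort_af(calls: Iterable[CandidateCall]) -> None:
    """Populate each call's cohort_af map from all calls at its (chrom, pos)."""
    site_af: dict[tuple[str, int], dict[str, float]] = {}
    calls = list(calls)
    for c in calls:
        if c.af is None:
            continue
        per_sample = site_af.setdefault((c.chrom, c.pos), {})
        per_sample[c.sample] = max(per_sample.get(c.sample, 0.0), c.af)
    for c in calls:
        c.cohort_af = dict(site_af.get((c.chrom, c.pos), {}))


# ---------------------------------------------------------------------------
# filters

def exclude_background(
    calls: Sequence[CandidateCall], share_min: int = 3
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Drop all calls at sites carried by >= ``share_min`` samples.

    Sites recurring across that many independent samples are pre-existing
    or artifactual, not independently induced mutations.
    """
    samples_at_site: dict[tuple[str, int], set[str]] = {}
    for c in calls:
        samples_at_site.setdefault((c.chrom, c.pos), set()).add(c.sample)
    kept, removed = [], []
    for c in calls:
        if len(samples_at_site[(c.chrom, c.pos)]) >= share_min:
            removed.append(c)
        else:
            kept.append(c)
    if removed:
        sites = sorted({(c.chrom, c.pos) for c in removed})
        logger.info("background exclusion removed %d calls at %d sites: %s",
                    len(removed), len(sites), sites[:20])
    return kept, removed


def filter_af(
    calls: Sequence[CandidateCall], af_min_exclusive: float = 0.25
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Drop calls with AF at or below the threshold (AF of 25% or less).

    Calls without an AF (symbolic SV records) pass through.
    """
    kept, removed = [], []
    for c in calls:
        if c.af is not None and c.af <= af_min_exclusive:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def filter_scanner_records(
    calls: Sequence[CandidateCall], min_len: int = 11
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Scanner-origin filters: minimum indel length and cross-sample uniqueness.

    Indel-scanner calls shorter than ``min_len`` (<= 10 bp by default) are
    removed — that size range belongs to the small-variant caller.
    Indel- and sv-scanner calls whose site appears in more than one
    sample are removed: scanner candidates must be unique to a single
    sample.  Small-variant calls pass through untouched.
    """
    scanner_sites: dict[tuple[str, str, int], set[str]] = {}
    for c in calls:
        if c.origin in (ORIGIN_INDEL, ORIGIN_SV):
            scanner_sites.setdefault((c.origin, c.chrom, c.pos), set()).add(c.sample)
    kept, removed = [], []
    for c in calls:
        if c.origin == ORIGIN_INDEL and c.variant_length < min_len:
            removed.append(c)
        elif (
            c.origin in (ORIGIN_INDEL, ORIGIN_SV)
            and len(scanner_sites[(c.origin, c.chrom, c.pos)]) > 1
        ):
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def call_zygosity(
    call: CandidateCall,
    af_min_exclusive: float = 0.25,
    af_homo_min: float = 0.80,
    af_other_max: float = 0.05,
) -> tuple[str, str | None]:
    """Zygosity from the mutant-read fraction, guarded by cohort AFs.

    Returns (status, reason): status is ``"homozygous"``, ``"heterozygous"``
    or ``"reject"`` (with the reason filled in).  Homozygous requires
    AF >= 80%; heterozygous requires 25% < AF < 80%; both require every
    other cohort sample to show AF < 5% at the site.
    """
    if call.af is None:
        return "reject", "no-af"
    other = call.max_other_af()
    if other >= af_other_max:
        return "reject", f"other-sample-af:{other:.3f}"
    if call.af >= af_homo_min:
        return HOMOZYGOUS, None
    if call.af > af_min_exclusive:
        return HETEROZYGOUS, None
    return "reject", f"low-af:{call.af:.3f}"


def assign_zygosity(
    calls: Sequence[CandidateCall], thresholds: Thresholds | None = None
) -> tuple[list[CandidateCall], list[dict]]:
    """Apply :func:`call_zygosity` to every call; reject the unresolvable."""
    th = thresholds or Thresholds()
    kept, rejected = [], []
    for c in calls:
        status, reason = call_zygosity(
            c, th.af_min_exclusive, th.af_homo_min, th.af_other_max
        )
        if status == "reject":
            rejected.append({"sample": c.sample, "chrom": c.chrom, "pos": c.pos,
                             "reason": reason})
        else:
            c.zygosity = status
            kept.append(c)
    return kept, rejected


# ---------------------------------------------------------------------------
# events

def _call_category(call: CandidateCall, sv_min_len: int = 100) -> str:
    if call.origin == ORIGIN_SV or call.sv_type in {"INV", "DUP", "TRA"}:
        return "SV"
    lr, la = len(call.ref), len(call.alt)
    if lr == la == 1:
        return "SBS"
    size = call.variant_length
    if size >= sv_min_len:
        return "SV"
    if lr > la:
        return "Del1" if size == 1 else "DelGE2"
    if la > lr:
        return "Ins1" if size == 1 else "InsGE2"
    raise UnclassifiableEventError(f"cannot classify call: {call!r}")


def call_to_event(call: CandidateCall, sv_min_len: int = 100) -> MutationEvent:
    """Wrap a single retained call as a classified MutationEvent."""
    if call.zygosity not in (HOMOZYGOUS, HETEROZYGOUS):
        raise UnclassifiableEventError(f"call lacks zygosity: {call!r}")
    category = _call_category(call, sv_min_len)
    if category == "SBS":
        size = 0
    else:
        size = call.variant_length
    return MutationEvent(
        sample=call.sample, chrom=call.chrom,
        start=call.start, end=call.end,
        category=category, zygosity=call.zygosity, size=size,
        members=[call], ref=call.ref, alt=call.alt,
    )


def _complex_event(chain: list[CandidateCall]) -> MutationEvent:
    start = min(c.start for c in chain)
    end = max(c.end for c in chain)
    return MutationEvent(
        sample=chain[0].sample, chrom=chain[0].chrom,
        start=start, end=end, category="Complex",
        zygosity=chain[0].zygosity, size=end - start + 1,
        members=list(chain),
        ref=",".join(c.ref for c in chain),
        alt=",".join(c.alt for c in chain),
    )


def classify_event(event: MutationEvent, sv_min_len: int = 100) -> str:
    """Category of an event: the seven-way classification.

    Complex takes precedence for multi-member events; otherwise the
    single member's caller origin, SV type and size decide.
    """
    if len(event.members) >= 2:
        return "Complex"
    return _call_category(event.members[0], sv_min_len)


def merge_complex(
    calls: Sequence[CandidateCall],
    gap: int = 10,
    min_members: int = 2,
    sv_min_len: int = 100,
) -> list[MutationEvent]:
    """Merge chains of nearby small mutations into complex events.

    Small-variant calls for one sample are chained along each chromosome:
    consecutive calls separated by fewer than ``gap`` intervening
    reference bases belong to one chain (chaining is transitive).  A
    chain of >= ``min_members`` calls of uniform zygosity becomes one
    Complex event spanning its members; mixed-zygosity chains are left
    unmerged (and logged), and all other calls pass through as singleton
    events.

    Scanner-origin calls (long indels, SVs) never participate in merging.
    """
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise ParameterDomainError("merge_complex operates on a single sample")
    mergeable = [c for c in calls if c.origin == ORIGIN_SMALL]
    passthrough = [c for c in calls if c.origin != ORIGIN_SMALL]

    events: list[MutationEvent] = []
    mergeable.sort(key=lambda c: (c.chrom, c.start, c.end))
    chain: list[CandidateCall] = []

    def flush(chain: list[CandidateCall]) -> None:
        if len(chain) >= min_members:
            if len({c.zygosity for c in chain}) == 1:
                events.append(_complex_event(chain))
                return
            logger.info(
                "mixed-zygosity chain at %s:%d-%d left unmerged",
                chain[0].chrom, chain[0].start, chain[-1].end,
            )
        events.extend(call_to_event(c, sv_min_len) for c in chain)

    for c in mergeable:
        if chain and c.chrom == chain[-1].chrom and (
            c.start - max(x.end for x in chain) - 1 < gap
        ):
            chain.append(c)
        else:
            if chain:
                flush(chain)
            chain = [c]
    if chain:
        flush(chain)

    events.extend(call_to_event(c, sv_min_len) for c in passthrough)
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return events


# ---------------------------------------------------------------------------
# pipeline

def events_to_dataframe(events: Sequence[MutationEvent]) -> pd.DataFrame:
    rows = [
        {
            "sample": e.sample, "chrom": e.chrom, "start": e.start, "end": e.end,
            "category": e.category, "zygosity": e.zygosity, "size": e.size,
            "members": e.n_members, "ref": e.ref, "alt": e.alt,
        }
        for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values(["sample", "chrom", "start", "end"]).reset_index(drop=True)


def run_pipeline(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[MutationEvent], dict]:
    """Run the full post-calling pipeline for a cohort.

    Returns (event table, event objects, audit).  The audit dict carries
    per-step input/kept/removed counts so every input call is accounted
    for; the table is deterministic for identical inputs.
    """
    th = config.thresholds
    audit: dict = {"steps": []}

    def step(name: str, n_in: int, n_kept: int) -> None:
        audit["steps"].append(
            {"step": name, "in": n_in, "kept": n_kept, "removed": n_in - n_kept}
        )

    try:
        vcfs = {s.name: s.vcfs for s in config.samples}
        calls, rej_load = load_candidates(vcfs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage identity
        raise PipelineError("load", str(exc)) from exc
    step("load", len(calls) + len(rej_load), len(calls))

    small = [c for c in calls if c.origin == ORIGIN_SMALL]
    scanner = [c for c in calls if c.origin != ORIGIN_SMALL]

    small_kept, bg_removed = exclude_background(small, th.background_share_min)
    step("background", len(small), len(small_kept))

    merged = small_kept + scanner
    af_kept, af_removed = filter_af(merged, th.af_min_exclusive)
    step("af-filter", len(merged), len(af_kept))

    sc_kept, sc_removed = filter_scanner_records(af_kept, th.scanner_min_len)
    step("scanner-filter", len(af_kept), len(sc_kept))

    zy_kept, zy_rejected = assign_zygosity(sc_kept, th)
    step("zygosity", len(sc_kept), len(zy_kept))

    events: list[MutationEvent] = []
    for s in config.samples:
        sample_calls = [c for c in zy_kept if c.sample == s.name]
        events.extend(
            merge_complex(
                sample_calls,
                gap=th.complex_gap,
                min_members=th.complex_min_members,
                sv_min_len=th.sv_min_len,
            )
        )
    step("merge+classify", len(zy_kept), sum(e.n_members for e in events))

    audit["n_input_calls"] = len(calls) + len(rej_load)
    audit["n_events"] = len(events)
    audit["rejected"] = {
        "load": rej_load,
        "zygosity": zy_rejected,
    }
    df = events_to_dataframe(events)
    return df, events, audit


def write_events_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
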