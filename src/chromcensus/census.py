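"""Post-processing of homology-search output for the chromatin-modifier census.

The census takes raw profile-HMM domain hits and pairwise-search HSPs and
applies the retention logic of the comparative screen:

* domain hits are kept only when they cover at least half of the model or of
  the hit protein (removing short, fragmented matches);
* HSPs of one query against one subject are merged — non-overlapping
  regions concatenated, redundant regions collapsed to their union — and the
  merged match is represented by the worst constituent e-value;
* merged matches survive only with e-value strictly below 1e-5 and strictly
  more than 50 % coverage of query or subject;
* when fewer than ten matches survive among the Aspergilli, the search is
  escalated to an iterative profile search seeded with the best Aspergilli
  hit (or the original query when none was retained);
* apparent absences are re-examined by translated genomic search: loci with
  e-value below 1e-5 are expanded by 4500 nt on both sides and scanned for
  open reading frames;
* proteins are assigned to enzyme families by their ordered Pfam domain
  architecture;
* alignment columns with gaps in more than 90 % of sequences are trimmed
  before tree inference.

All inequalities are strict, following the screen's wording ("lower than",
"more than").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io import BlastTabRecord, DomtblRecord, Msa, ProteinRecord


@dataclass(frozen=True)
class CensusConfig:
    """Thresholds of the census screen; defaults are the screen's values."""

    hmm_cov_min: float = 0.5        # min model-or-hit length coverage for domain hits
    blastp_initial_evalue: float = 1e-2   # search-time cutoff (metadata only)
    final_evalue: float = 1e-5      # strict retention threshold for merged matches
    match_cov_min: float = 0.5      # strict query-or-subject coverage threshold
    escalation_min_hits: int = 10   # escalate when fewer Aspergilli matches survive
    psiblast_iterations: int = 5    # iterations of the escalated search (metadata)
    rescue_evalue: float = 1e-5     # strict threshold for genomic rescue loci
    flank_nt: int = 4500            # nt added on both sides of a rescue locus
    trim_max_gap_fraction: float = 0.9   # drop columns with gap fraction above this
    evalue_rule: str = "worst"      # representative e-value of a merged match
    rescue_min_codons: int = 50     # ORF length floor for the single-exon fallback

    def __post_init__(self):
        for name in ("hmm_cov_min", "match_cov_min", "trim_max_gap_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.flank_nt < 0:
            raise ValueError("flank_nt must be >= 0")
        if self.evalue_rule not in ("worst", "best"):
            raise ValueError("evalue_rule must be 'worst' or 'best'")


# ---------------------------------------------------------------------------
# intervals

@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive span on a sequence."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval {self.start}..{self.end} inverted")

    def __len__(self) -> int:
        return self.end - self.start + 1


def union_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Collapse intervals to a sorted, pairwise-disjoint union.

    Adjacent intervals (end + 1 == next start) are joined: positions covered
    form one contiguous run.
    """
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end + 1:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


def compute_coverage(intervals: Sequence[Interval], seq_len: int) -> float:
    """Fraction of a sequence of length ``seq_len`` covered by the intervals."""
    if seq_len < 1:
        raise ValueError(f"seq_len must be >= 1, got {seq_len}")
    merged = union_intervals(intervals)
    for iv in merged:
        if iv.end > seq_len or iv.start < 1:
            raise ValueError(f"interval {iv.start}..{iv.end} exceeds length {seq_len}")
    return sum(len(iv) for iv in merged) / seq_len


# ---------------------------------------------------------------------------
# domain-hit filtering

def filter_domain_hits(
    hits: Sequence[DomtblRecord], cfg: CensusConfig = CensusConfig()
) -> list[DomtblRecord]:
    """Drop short/incomplete domain hits.

    A hit is retained iff it covers at least ``hmm_cov_min`` of the model
    (query domain) OR of the hit protein. Input order is preserved.
    """
    return [
        h for h in hits
        if h.hmm_coverage >= cfg.hmm_cov_min or h.target_coverage >= cfg.hmm_cov_min
    ]


# ---------------------------------------------------------------------------
# HSP merging and match filtering

@dataclass(frozen=True)
class MergedMatch:
    """Union of all HSPs of one query against one subject.

    Non-overlapping regions are concatenated; overlapping regions are kept
    once (only the non-redundant region counts toward coverage). The merged
    match is represented by the numerically largest (worst) constituent
    e-value by default — the most conservative significance.
    """

    query_id: str
    subject_id: str
    query_intervals: tuple[Interval, ...]
    subject_intervals: tuple[Interval, ...]
    representative_evalue: float
    query_len: int
    subject_len: int

    @property
    def coverage_query(self) -> float:
        return compute_coverage(self.query_intervals, self.query_len)

    @property
    def coverage_subject(self) -> float:
        return compute_coverage(self.subject_intervals, self.subject_len)


def merge_hsps(
    hsps: Sequence[BlastTabRecord],
    query_len: int,
    subject_len: int,
    cfg: CensusConfig = CensusConfig(),
) -> MergedMatch:
    """Merge the HSPs of one (query, subject) pair into a single match."""
    if not hsps:
        raise ValueError("merge_hsps requires at least one HSP")
    pairs = {(h.qseqid, h.sseqid) for h in hsps}
    if len(pairs) > 1:
        raise ValueError(f"HSPs span multiple query/subject pairs: {sorted(pairs)}")
    q_ivs = union_intervals(Interval(h.qstart, h.qend) for h in hsps)
    s_ivs = union_intervals(Interval(h.sstart, h.send) for h in hsps)
    evalues = [h.evalue for h in hsps]
    rep = max(evalues) if cfg.evalue_rule == "worst" else min(evalues)
    (qid, sid), = pairs
    return MergedMatch(qid, sid, q_ivs, s_ivs, rep, query_len, subject_len)


def merge_all_hsps(
    records: Sequence[BlastTabRecord],
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
    cfg: CensusConfig = CensusConfig(),
) -> list[MergedMatch]:
    """Group records by (query, subject) and merge each group."""
    groups: dict[tuple[str, str], list[BlastTabRecord]] = {}
    for r in records:
        groups.setdefault((r.qseqid, r.sseqid), []).append(r)
    out = []
    for (qid, sid), hsps in groups.items():
        out.append(merge_hsps(hsps, query_lengths[qid], subject_lengths[sid], cfg))
    return out


def filter_matches(
    matches: Sequence[MergedMatch], cfg: CensusConfig = CensusConfig()
) -> list[MergedMatch]:
    """Retain merged matches with e-value strictly below ``final_evalue`` and
    strictly more than ``match_cov_min`` coverage of the query or the subject."""
    return [
        m for m in matches
        if m.representative_evalue < cfg.final_evalue
        and (m.coverage_query > cfg.match_cov_min
             or m.coverage_subject > cfg.match_cov_min)
    ]


# ---------------------------------------------------------------------------
# search escalation

@dataclass(frozen=True)
class EscalationPlan:
    escalate: bool
    next_query_id: str


def default_species_of(subject_id: str) -> str:
    """Species of a subject protein, from the ``species|protein`` id scheme."""
    return subject_id.split("|", 1)[0]


def escalation_decision(
    retained: Sequence[MergedMatch],
    aspergilli_species: set[str],
    original_query_id: str,
    cfg: CensusConfig = CensusConfig(),
    species_of: Callable[[str], str] = default_species_of,
) -> EscalationPlan:
    """Decide whether to escalate to the iterative profile search.

    Escalate when fewer than ``escalation_min_hits`` retained matches fall in
    Aspergilli. The escalated search is seeded with the best Aspergilli hit
    (smallest e-value; ties broken by larger query coverage, then
    lexicographic subject id), or with the original query when no Aspergilli
    match was retained.
    """
    asp = [m for m in retained if species_of(m.subject_id) in aspergilli_species]
    escalate = len(asp) < cfg.escalation_min_hits
    if not asp:
        return EscalationPlan(escalate, original_query_id)
    best = min(asp, key=lambda m: (m.representative_evalue,
                                   -m.coverage_query, m.subject_id))
    return EscalationPlan(escalate, best.subject_id)


def join_match_sets(
    primary: Sequence[MergedMatch], secondary: Sequence[MergedMatch]
) -> list[MergedMatch]:
    """Join two filtered match sets, keyed by subject id.

    On collision the entry with the smaller representative e-value wins;
    ties go to the larger coverage (query, then subject).
    """
    def rank(m: MergedMatch):
        return (m.representative_evalue, -m.coverage_query, -m.coverage_subject)

    best: dict[str, MergedMatch] = {}
    for m in list(primary) + list(secondary):
        cur = best.get(m.subject_id)
        if cur is None or rank(m) < rank(cur):
            best[m.subject_id] = m
    return list(best.values())


# ---------------------------------------------------------------------------
# genomic rescue

@dataclass(frozen=True)
class LocusWindow:
    """A genomic locus (with flanks) that may hide an unannotated gene."""

    contig_id: str
    start: int
    end: int
    strand: str
    source_evalues: tuple[float, ...]
    query_id: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"window {self.start}..{self.end} invalid")


def rescue_windows(
    tblastn_hits: Sequence[BlastTabRecord],
    contig_lengths: Mapping[str, int],
    cfg: CensusConfig = CensusConfig(),
) -> list[LocusWindow]:
    """Turn significant translated-genomic hits into flanked loci.

    Hits with e-value strictly below ``rescue_evalue`` are expanded by
    ``flank_nt`` on both sides, clamped to the contig; overlapping windows
    on the same contig and strand are merged, concatenating their e-values.
    """
    prelim: dict[tuple[str, str, str], list[LocusWindow]] = {}
    for h in tblastn_hits:
        if h.evalue >= cfg.rescue_evalue:
            continue
        if h.sseqid not in contig_lengths:
            raise KeyError(f"unknown contig {h.sseqid!r}")
        clen = contig_lengths[h.sseqid]
        start = max(1, h.sstart - cfg.flank_nt)
        end = min(clen, h.send + cfg.flank_nt)
        w = LocusWindow(h.sseqid, start, end, h.strand, (h.evalue,), h.qseqid)
        prelim.setdefault((h.sseqid, h.strand, h.qseqid), []).append(w)

    out: list[LocusWindow] = []
    for (contig, strand, query), windows in prelim.items():
        windows.sort(key=lambda w: (w.start, w.end))
        merged: list[LocusWindow] = []
        for w in windows:
            if merged and w.start <= merged[-1].end:
                prev = merged[-1]
                merged[-1] = LocusWindow(
                    contig, prev.start, max(prev.end, w.end), strand,
                    prev.source_evalues + w.source_evalues, query,
                )
            else:
                merged.append(w)
        out.extend(merged)
    return out


def single_exon_rescue(
    window: LocusWindow,
    contig_seq: str,
    cfg: CensusConfig = CensusConfig(),
) -> list[ProteinRecord]:
    """Translate all long ORFs in a rescue window (single-exon fallback).

    Scans the six reading frames of the window for ATG-initiated open
    reading frames of at least ``rescue_min_codons`` codons, translated with
    the standard genetic code; candidates are ordered by length descending.
    This deliberately ignores introns — a spliced aligner producing candidate
    proteins for a window can be plugged in through the same contract.
    """
    if window.end > len(contig_seq):
        raise ValueError("window exceeds contig length")
    sub = contig_seq[window.start - 1:window.end].upper()
    candidates: list[ProteinRecord] = []
    n = 0
    for strand_seq, strand in ((sub, "+"), (str(Seq(sub).reverse_complement()), "-")):
        for frame in range(3):
            aa = str(Seq(strand_seq[frame:frame + (len(strand_seq) - frame) // 3 * 3]
                         ).translate())
            i = 0
            while i < len(aa):
                if aa[i] == "M":
                    stop = aa.find("*", i)
                    orf = aa[i:stop if stop != -1 else len(aa)]
                    if stop != -1 and len(orf) >= cfg.rescue_min_codons:
                        n += 1
                        pid = (f"{window.contig_id}:{window.start}-{window.end}"
                               f":{strand}{frame + 1}:orf{n}")
                        candidates.append(
                            ProteinRecord(pid, window.contig_id.split("|")[0], orf)
                        )
                    i = (stop + 1) if stop != -1 else len(aa)
                else:
                    i += 1
    candidates.sort(key=lambda r: (-r.length, r.protein_id))
    return candidates


# ---------------------------------------------------------------------------
# domain-architecture classification

@dataclass(frozen=True)
class ArchitectureRule:
    """A family definition: Pfam domains that must (and must not) co-occur."""

    family_name: str
    required_domains: frozenset[str]
    forbidden_domains: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self):
        if not self.required_domains:
            raise ValueError(f"{self.family_name}: required set empty")
        if self.required_domains & self.forbidden_domains:
            raise ValueError(f"{self.family_name}: required and forbidden overlap")

    def matches(self, architecture: Iterable[str]) -> bool:
        arch = set(architecture)
        return (self.required_domains <= arch
                and not (self.forbidden_domains & arch))


def _rule(name, required, forbidden=(), priority=0):
    return ArchitectureRule(name, frozenset(required), frozenset(forbidden), priority)


#: Family definitions for the chromatin-modifier census. Priorities put rules
#: with larger required sets first so supersets are never shadowed by their
#: subsets (SET2 over Ash1, Elp3 over a bare GNAT domain).
DEFAULT_RULES: tuple[ArchitectureRule, ...] = (
    # DNA methyltransferase with SNF2-family helicase module
    _rule("DNMT5", {"PF00145", "PF00176", "PF00271"}, priority=30),
    # SET-domain histone methyltransferases
    _rule("SET1", {"PF00856", "PF11764", "PF11767"}, priority=29),
    _rule("SET2", {"PF00856", "PF17907", "PF08236"}, priority=28),
    _rule("Ash1", {"PF00856", "PF17907"}, forbidden={"PF08236"}, priority=20),
    _rule("Dim-5", {"PF00856", "PF05033"}, priority=19),
    _rule("RKMT", {"PF00856", "PF09273"}, priority=18),  # ribosomal lysine N-MTase
    # GNAT acetyltransferases
    _rule("Elp3", {"PF00583", "PF04055", "PF16199"}, priority=27),
    _rule("Gcn5", {"PF00583", "PF00439"}, priority=17),
    # MYST acetyltransferases
    _rule("Sas3", {"PF01853", "PF17772"}, priority=16),
    _rule("Sas2", {"PF01853", "PF16866"}, priority=15),
    _rule("Esa1", {"PF01853", "PF11717"}, priority=14),
    # class II histone deacetylase with Arb2 anchor
    _rule("HdaA", {"PF00850", "PF09757"}, priority=13),
)

#: Catalytic domains used to label unmatched architectures by superfamily.
_CATALYTIC_PREFIX = {
    "PF00856": "SET",
    "PF00145": "DNMT",
    "PF00583": "GNAT",
    "PF01853": "MYST",
    "PF00850": "HDAC",
    "PF02373": "JmjC",
}

UNCLASSIFIED = "UNCLASSIFIED"


def assemble_architecture(hits: Sequence[DomtblRecord]) -> tuple[str, ...]:
    """Ordered domain string of one protein from its (filtered) domain hits.

    Domains are sorted by envelope start; overlapping hits of the same
    accession collapse to one occurrence.
    """
    targets = {h.target_id for h in hits}
    if len(targets) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(targets)}")
    ordered = sorted(hits, key=lambda h: (h.env_from, h.env_to))
    arch: list[str] = []
    last_end: dict[str, int] = {}
    for h in ordered:
        if arch and arch[-1] == h.domain_id and h.env_from <= last_end[h.domain_id]:
            last_end[h.domain_id] = max(last_end[h.domain_id], h.env_to)
            continue
        arch.append(h.domain_id)
        last_end[h.domain_id] = h.env_to
    return tuple(arch)


def classify_family(
    architecture: Iterable[str],
    rules: Sequence[ArchitectureRule] = DEFAULT_RULES,
) -> str:
    """Assign a family label to a domain architecture.

    The highest-priority rule whose required domains are all present and
    whose forbidden domains are all absent wins; otherwise the protein is
    labelled by its catalytic superfamily ("SET-unclassified", ...) or
    UNCLASSIFIED. Deterministic and total: exactly one label per protein.
    """
    arch = set(architecture)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("architecture rules must have distinct priorities")
    for rule in sorted(rules, key=lambda r: -r.priority):
        if rule.matches(arch):
            return rule.family_name
    for acc, prefix in _CATALYTIC_PREFIX.items():
        if acc in arch:
            return f"{prefix}-unclassified"
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# presence calls

class Evidence(enum.Enum):
    """Provenance of a presence call, best tier first."""

    DOMAIN_SCAN = 1
    BLASTP = 2
    PSIBLAST = 3
    RESCUE = 4
    ABSENT = 5


@dataclass(frozen=True)
class PresenceCall:
    species_id: str
    family_or_subunit: str
    present: bool
    evidence: Evidence
    supporting_ids: tuple[str, ...]

    def __post_init__(self):
        if self.present != (self.evidence != Evidence.ABSENT):
            raise ValueError("present flag inconsistent with evidence tier")
        if self.present != bool(self.supporting_ids):
            raise ValueError("supporting ids must be nonempty iff present")


EvidenceMap = Mapping[tuple[str, str], Sequence[str]]


def call_presence(
    domain_scan: EvidenceMap | None = None,
    blastp: EvidenceMap | None = None,
    psiblast: EvidenceMap | None = None,
    rescue: EvidenceMap | None = None,
    grid: tuple[Sequence[str], Sequence[str]] | None = None,
) -> list[PresenceCall]:
    """Combine evidence tiers into one presence call per (species, target).

    Each map keys (species_id, family_or_subunit) to supporting protein or
    locus ids. The best nonempty tier (domain scan > pairwise search >
    iterative search > genomic rescue) wins. When ``grid`` (species ids,
    target names) is given, pairs without evidence yield explicit ABSENT
    calls; otherwise only evidenced pairs are reported.
    """
    tiers = [
        (Evidence.DOMAIN_SCAN, domain_scan or {}),
        (Evidence.BLASTP, blastp or {}),
        (Evidence.PSIBLAST, psiblast or {}),
        (Evidence.RESCUE, rescue or {}),
    ]
    keys: set[tuple[str, str]] = set()
    for _, m in tiers:
        keys.update(k for k, v in m.items() if v)
    if grid is not None:
        species_ids, targets = grid
        keys.update((s, t) for s in species_ids for t in targets)
    calls = []
    for species, target in sorted(keys):
        for tier, m in tiers:
            ids = tuple(m.get((species, target), ()))
            if ids:
                calls.append(PresenceCall(species, target, True, tier, ids))
                break
        else:
            calls.append(PresenceCall(species, target, False, Evidence.ABSENT, ()))
    return calls


# ---------------------------------------------------------------------------
# alignment trimming

def trim_alignment_columns(msa: Msa, cfg: CensusConfig = CensusConfig()) -> Msa:
    """Remove alignment columns with gaps in more than 90 % of the sequences.

    A column is kept iff its gap fraction is <= ``trim_max_gap_fraction``
    (a column gapped in exactly 90 % of sequences stays)."""
    if not msa.records:
        return msa
    n = len(msa.records)
    keep = []
    for col in range(msa.n_columns):
        gaps = sum(1 for _, seq in msa.records if seq[col] == "-")
        if gaps / n <= cfg.trim_max_gap_fraction:
            keep.append(col)
    new_records = tuple(
        (name, "".join(seq[c] for c in keep)) for name, seq in msa.records
    )
    return Msa(new_records)
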