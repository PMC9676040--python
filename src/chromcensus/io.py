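"""Readers and writers for the standard formats the census pipeline touches.

Every downstream module consumes only the typed records defined here:
protein FASTA, HMMER per-domain tabular output (domtblout), BLAST tabular
output (outfmt 6, 12 columns), Newick species trees with group labels, and
the peptide AUC tables of the mass-spectrometry workflow.

All coordinates are 1-based inclusive, matching the HMMER and BLAST
conventions; conversions to 0-based happen only inside consumers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed input row; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# record types

_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein from a per-species proteome."""

    protein_id: str
    species_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_AA
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: non-canonical residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: ordered (id, gapped sequence) pairs."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: column counts {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0


@dataclass(frozen=True)
class DomtblRecord:
    """One per-domain row of HMMER's domtblout table.

    Both the full-sequence e-value and the per-domain independent e-value
    are retained; filtering downstream uses ``i_evalue`` by default.
    """

    target_id: str
    target_len: int
    domain_id: str
    hmm_len: int
    i_evalue: float
    hmm_from: int
    hmm_to: int
    env_from: int
    env_to: int
    full_evalue: float = 0.0

    def __post_init__(self):
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_len):
            raise ValueError(
                f"{self.target_id}/{self.domain_id}: bad model coordinates "
                f"{self.hmm_from}..{self.hmm_to} on model length {self.hmm_len}"
            )
        if not (1 <= self.env_from <= self.env_to <= self.target_len):
            raise ValueError(
                f"{self.target_id}/{self.domain_id}: bad envelope coordinates "
                f"{self.env_from}..{self.env_to} on target length {self.target_len}"
            )
        if self.i_evalue < 0 or self.full_evalue < 0:
            raise ValueError(f"{self.target_id}: negative e-value")

    @property
    def hmm_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_len

    @property
    def target_coverage(self) -> float:
        return (self.env_to - self.env_from + 1) / self.target_len


@dataclass(frozen=True)
class BlastTabRecord:
    """One row of BLAST tabular output (outfmt 6, 12 standard columns).

    Minus-strand nucleotide subjects (TBLASTN) are normalized at parse time:
    ``sstart <= send`` always holds and ``strand`` records the orientation.
    """

    qseqid: str
    sseqid: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if self.qstart > self.qend:
            raise ValueError(f"{self.qseqid}: qstart {self.qstart} > qend {self.qend}")
        if self.sstart > self.send:
            raise ValueError("subject coordinates must be normalized (sstart <= send)")
        if self.evalue < 0:
            raise ValueError(f"{self.qseqid}: negative e-value")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class SpeciesEntry:
    species_id: str
    group: str  # ASPERGILLI or OUTGROUP
    section_label: str
    tree_order_index: int


ASPERGILLI = "ASPERGILLI"
OUTGROUP = "OUTGROUP"


@dataclass(frozen=True)
class SpeciesCatalog:
    """The species panel in species-tree leaf order with group labels."""

    entries: tuple[SpeciesEntry, ...]

    def __post_init__(self):
        idx = sorted(e.tree_order_index for e in self.entries)
        if idx != list(range(len(self.entries))):
            raise ValueError("tree_order_index must be a permutation of 0..n-1")
        ids = [e.species_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in catalog")

    @property
    def species_ids(self) -> list[str]:
        return [e.species_id for e in sorted(self.entries, key=lambda e: e.tree_order_index)]

    def group_of(self, species_id: str) -> str:
        for e in self.entries:
            if e.species_id == species_id:
                return e.group
        raise KeyError(species_id)

    def in_group(self, group: str) -> list[str]:
        return [e.species_id for e in sorted(self.entries, key=lambda e: e.tree_order_index)
                if e.group == group]


@dataclass(frozen=True)
class AucObservation:
    """One quantified modified-peptide form: its XIC area and id scores."""

    histone_id: str
    span_start: int
    span_end: int
    form_label: str
    auc: float
    andromeda_score: float
    localization_prob: float

    def __post_init__(self):
        if self.span_start > self.span_end:
            raise ValueError(
                f"{self.histone_id}: span {self.span_start}..{self.span_end} inverted"
            )
        if self.auc < 0:
            raise ValueError(f"{self.histone_id} {self.form_label}: negative AUC")
        if not (0.0 <= self.localization_prob <= 1.0):
            raise ValueError(
                f"{self.histone_id} {self.form_label}: localization probability "
                f"{self.localization_prob} outside [0, 1]"
            )
        # validate the modification-form grammar (deferred import: the grammar
        # lives with the MS model)
        from .histone import parse_form_label

        parse_form_label(self.form_label, span=(self.span_start, self.span_end))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into typed records.

    ``species_id`` defaults to the file stem (per-proteome files carry the
    species implicitly); pass it explicitly to override.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate protein id {rec.id!r} in {path.name}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, species_id, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_msa_fasta(path: str | Path) -> Msa:
    recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ParseError(f"no alignment records in {path}")
    return Msa(tuple(recs))


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# HMMER domtblout

def read_domtblout(path: str | Path) -> list[DomtblRecord]:
    """Parse HMMER's whitespace-delimited per-domain table.

    Column layout follows hmmsearch --domtblout: target name/acc/tlen, query
    name/acc/qlen, full-sequence E-value/score/bias, domain index, c-Evalue,
    i-Evalue, scores, hmm from/to, ali from/to, env from/to.
    """
    records: list[DomtblRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 21:
                raise ParseError(
                    f"domtblout row has {len(cols)} columns, need at least 21",
                    line=lineno,
                )
            try:
                domain_id = cols[4] if cols[4] != "-" else cols[3]
                rec = DomtblRecord(
                    target_id=cols[0],
                    target_len=int(cols[2]),
                    domain_id=domain_id,
                    hmm_len=int(cols[5]),
                    full_evalue=float(cols[6]),
                    i_evalue=float(cols[12]),
                    hmm_from=int(cols[15]),
                    hmm_to=int(cols[16]),
                    env_from=int(cols[19]),
                    env_to=int(cols[20]),
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            records.append(rec)
    return records


def write_domtblout(records: Iterable[DomtblRecord], path: str | Path,
                    comment: str | None = None) -> None:
    """Write records back in the domtblout column layout (unused columns '-')."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# target tlen query qacc qlen E-value score bias # of "
                 "c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc\n")
        for r in records:
            fh.write(
                f"{r.target_id} - {r.target_len} {r.domain_id} {r.domain_id} "
                f"{r.hmm_len} {r.full_evalue:.3g} 0.0 0.0 1 1 "
                f"{r.i_evalue:.3g} {r.i_evalue:.3g} 0.0 0.0 "
                f"{r.hmm_from} {r.hmm_to} {r.env_from} {r.env_to} "
                f"{r.env_from} {r.env_to} 0.90\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular

def read_blast_tab(path: str | Path) -> list[BlastTabRecord]:
    """Parse 12-column BLAST tabular output (outfmt 6) in file order."""
    records: list[BlastTabRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(cols)}", line=lineno
                )
            try:
                sstart, send = int(cols[8]), int(cols[9])
                strand = "+" if sstart <= send else "-"
                rec = BlastTabRecord(
                    qseqid=cols[0],
                    sseqid=cols[1],
                    pident=float(cols[2]),
                    aln_len=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=min(sstart, send),
                    send=max(sstart, send),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    strand=strand,
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            records.append(rec)
    return records


def write_blast_tab(records: Iterable[BlastTabRecord], path: str | Path,
                    comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for r in records:
            s1, s2 = (r.sstart, r.send) if r.strand == "+" else (r.send, r.sstart)
            fh.write(
                f"{r.qseqid}\t{r.sseqid}\t{r.pident:.1f}\t{r.aln_len}\t"
                f"{r.mismatch}\t{r.gapopen}\t{r.qstart}\t{r.qend}\t"
                f"{s1}\t{s2}\t{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Newick species tree

def read_newick_groups(
    path: str | Path,
    group_map: Mapping[str, str | tuple[str, str]],
) -> SpeciesCatalog:
    """Read a Newick tree and attach group/section labels to its leaves.

    ``group_map`` maps every leaf label to a group (ASPERGILLI / OUTGROUP) or
    a (group, section_label) pair. Leaf order of a fixed left-to-right
    traversal defines ``tree_order_index``.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    leaves = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in group_map]
    if missing:
        raise ParseError(f"leaves missing from group map: {missing}")
    entries = []
    for i, leaf in enumerate(leaves):
        val = group_map[leaf]
        if isinstance(val, tuple):
            group, section = val
        else:
            group, section = val, ""
        entries.append(SpeciesEntry(leaf, group, section, i))
    return SpeciesCatalog(tuple(entries))


# ---------------------------------------------------------------------------
# AUC tables

AUC_HEADER = ["histone", "span_start", "span_end", "form", "auc", "score", "loc_prob"]


def read_auc_table(path: str | Path) -> list[AucObservation]:
    """Read a peptide AUC table (CSV with the documented header)."""
    obs: list[AucObservation] = []
    with open(path) as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != AUC_HEADER:
            raise ParseError(
                f"AUC table header must be {','.join(AUC_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                obs.append(
                    AucObservation(
                        histone_id=row["histone"].strip(),
                        span_start=int(row["span_start"]),
                        span_end=int(row["span_end"]),
                        form_label=row["form"].strip(),
                        auc=float(row["auc"]),
                        andromeda_score=float(row["score"]),
                        localization_prob=float(row["loc_prob"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return obs


def write_auc_table(obs: Iterable[AucObservation], path: str | Path,
                    comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh)
        writer.writerow(AUC_HEADER)
        for o in obs:
            writer.writerow(
                [o.histone_id, o.span_start, o.span_end, o.form_label,
                 repr(o.auc), repr(o.andromeda_score), repr(o.localization_prob)]
            )


# ---------------------------------------------------------------------------
# presence/absence TSV (tokens: 1 present, 0 absent, R rescued)

def write_pap_tsv(matrix, path: str | Path) -> None:
    """Write a presence/absence matrix as TSV: header = species in tree order,
    one row per subunit; cells are 1 / 0 / R (R = presence recovered by the
    genomic rescue search)."""
    with open(path, "w") as fh:
        fh.write("subunit\t" + "\t".join(matrix.cols) + "\n")
        for row in matrix.rows:
            tokens = [matrix.token(row, col) for col in matrix.cols]
            fh.write(row + "\t" + "\t".join(tokens) + "\n")


def read_pap_tsv(path: str | Path):
    """Re-read a matrix written by :func:`write_pap_tsv` (lossless)."""
    from .pap import CellState, PapMatrix

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "subunit":
        raise ParseError("first header column must be 'subunit'", line=1)
    cols = header[1:]
    rows = []
    cells = {}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(cols) + 1:
            raise ParseError(
                f"expected {len(cols) + 1} columns, got {len(parts)}", line=lineno
            )
        row = parts[0]
        rows.append(row)
        for col, tok in zip(cols, parts[1:]):
            try:
                cells[(row, col)] = CellState.from_token(tok)
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return PapMatrix(tuple(rows), tuple(cols), cells)
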