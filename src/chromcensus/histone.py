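"""In-silico model of the bottom-up histone-PTM workflow.

The wet workflow derivatizes histones with propionic anhydride (propionyl on
unmodified and monomethylated lysine side chains), digests with trypsin —
which, with lysines blocked, cleaves only C-terminal of arginine (Arg-C
specificity) — and derivatizes peptide N-termini with phenyl isocyanate
(PIC). Each lysine of a peptide therefore occurs in exactly one of five
states:

====== ==================================== ==================
state  chemistry on the side chain          mass delta (Da)
====== ==================================== ==================
pr     propionyl (biologically unmodified)  +56.02621 (C3H4O)
me1    monomethyl + propionyl               +70.04186 (C4H6O)
me2    dimethyl                             +28.03130 (C2H4)
me3    trimethyl                            +42.04695 (C3H6)
ac     acetyl                               +42.01057 (C2H2O)
====== ==================================== ==================

This module enumerates the modified forms of each Arg-C peptide, computes
their monoisotopic masses and doubly-charged precursor m/z, filters
identifications on search-engine score and localization probability (both
strict), and converts XIC areas (AUC) into percent relative abundance (%RA)
per peptide span: the AUC of one form divided by the summed AUC of all
observed forms of that peptide, times 100.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

from .io import AucObservation, ProteinRecord


@dataclass(frozen=True)
class MsConfig:
    """Digestion, identification and quantification parameters."""

    max_missed_cleavages: int = 2
    min_peptide_len: int = 4
    precursor_ppm: float = 6.0
    xic_ppm: float = 10.0
    min_andromeda_score: float = 50.0
    min_localization_prob: float = 0.75
    charge: int = 2
    max_modifiable_K: int = 6

    def __post_init__(self):
        if self.max_missed_cleavages < 0 or self.min_peptide_len < 1:
            raise ValueError("invalid digestion parameters")
        for name in ("precursor_ppm", "xic_ppm", "min_andromeda_score",
                     "min_localization_prob", "charge", "max_modifiable_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# digestion

@dataclass(frozen=True)
class PeptideSpan:
    """An Arg-C peptide located on its histone (1-based inclusive)."""

    histone_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with coordinates")
        internal_r = self.sequence[:-1].count("R")
        if internal_r != self.missed_cleavages:
            raise ValueError(
                f"{self.histone_id} {self.start}-{self.end}: internal R count "
                f"{internal_r} != missed_cleavages {self.missed_cleavages}"
            )

    @property
    def k_positions(self) -> tuple[int, ...]:
        """Protein coordinates of the lysines in this peptide."""
        return tuple(
            self.start + i for i, aa in enumerate(self.sequence) if aa == "K"
        )


def digest_argc(protein: ProteinRecord, cfg: MsConfig = MsConfig()) -> list[PeptideSpan]:
    """Digest with Arg-C specificity: cleavage strictly C-terminal of every R
    (no proline exception), allowing up to ``max_missed_cleavages`` internal
    arginines; peptides shorter than ``min_peptide_len`` are dropped."""
    seq = protein.sequence
    cut_after = [i for i, aa in enumerate(seq) if aa == "R"]
    # fragment boundaries: starts follow each cut; the C-terminus always ends
    # a fragment whether or not it is R
    starts = [0] + [i + 1 for i in cut_after if i + 1 < len(seq)]
    ends = [i for i in cut_after] + ([len(seq) - 1] if not seq.endswith("R") else [])
    ends = sorted(set(ends))
    spans: list[PeptideSpan] = []
    for i, s in enumerate(starts):
        for mc in range(cfg.max_missed_cleavages + 1):
            j = i + mc
            if j >= len(ends):
                break
            e = ends[j]
            if e - s + 1 < cfg.min_peptide_len:
                continue
            spans.append(
                PeptideSpan(protein.protein_id, s + 1, e + 1, seq[s:e + 1], mc)
            )
    return spans


# ---------------------------------------------------------------------------
# modified-form enumeration

class KState(enum.Enum):
    """The five derivatized lysine states, in canonical enumeration order."""

    PR = "pr"
    ME1PR = "me1"
    ME2 = "me2"
    ME3 = "me3"
    AC = "ac"


#: elemental composition added per state (relative to unmodified lysine)
STATE_FORMULA = {
    KState.PR: "C3H4O",     # propionyl
    KState.ME1PR: "C4H6O",  # methyl + propionyl
    KState.ME2: "C2H4",     # two methyls
    KState.ME3: "C3H6",     # three methyls
    KState.AC: "C2H2O",     # acetyl (blocks propionylation)
}

PIC_FORMULA = "C7H5NO"  # phenyl isocyanate adduct on the peptide N-terminus
PROTON_MASS = 1.00727646

STATE_DELTA = {s: _pmass.calculate_mass(formula=f) for s, f in STATE_FORMULA.items()}
PIC_DELTA = _pmass.calculate_mass(formula=PIC_FORMULA)
_WATER = _pmass.calculate_mass(formula="H2O")

_TOKEN_RE = re.compile(r"^K(\d+)(pr|me1|me2|me3|ac)$")


@dataclass(frozen=True)
class ModForm:
    """One peptide span in one complete lysine-modification state."""

    span: PeptideSpan
    k_states: Mapping[int, KState]  # protein position -> state

    def __post_init__(self):
        if set(self.k_states) != set(self.span.k_positions):
            raise ValueError(
                "every lysine of the span needs exactly one state: "
                f"have {sorted(self.k_states)}, need {self.span.k_positions}"
            )

    @property
    def label(self) -> str:
        if not self.k_states:
            return "unmod"
        return "+".join(
            f"K{pos}{self.k_states[pos].value}" for pos in sorted(self.k_states)
        )


def parse_form_label(
    label: str, span: tuple[int, int] | None = None
) -> dict[int, KState]:
    """Parse a canonical form label ("K9me2+K14pr", or "unmod").

    Positions must be strictly ascending and unique; with ``span`` given they
    must fall inside it. Unknown states (e.g. a tetra-methylation "me4") are
    rejected.
    """
    if label == "unmod":
        return {}
    states: dict[int, KState] = {}
    last = 0
    for token in label.split("+"):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError(f"bad modification token {token!r} in {label!r}")
        pos = int(m.group(1))
        if pos <= last:
            raise ValueError(f"positions must be ascending and unique in {label!r}")
        last = pos
        if span is not None and not (span[0] <= pos <= span[1]):
            raise ValueError(f"position K{pos} outside span {span[0]}-{span[1]}")
        states[pos] = KState(m.group(2))
    return states


def enumerate_forms(span: PeptideSpan, cfg: MsConfig = MsConfig()) -> list[ModForm]:
    """All 5^k modification states of a span with k lysines, in deterministic
    order (positions ascending, states in the order pr, me1, me2, me3, ac)."""
    ks = span.k_positions
    if len(ks) > cfg.max_modifiable_K:
        raise ValueError(
            f"{span.histone_id} {span.start}-{span.end} has {len(ks)} lysines "
            f"(> {cfg.max_modifiable_K}); split the span or raise max_modifiable_K"
        )
    forms = []
    for combo in itertools.product(list(KState), repeat=len(ks)):
        forms.append(ModForm(span, dict(zip(ks, combo))))
    return forms


# ---------------------------------------------------------------------------
# masses

@dataclass(frozen=True)
class FormMass:
    monoisotopic_mass: float
    mz: float


def form_mass(form: ModForm, cfg: MsConfig = MsConfig()) -> FormMass:
    """Monoisotopic mass and precursor m/z of a derivatized peptide form.

    mass = sum of residue monoisotopic masses + water + PIC (fixed peptide
    N-terminal derivatization) + per-lysine state delta;
    m/z = (mass + z * proton) / z for the configured charge.
    """
    seq = form.span.sequence
    if not seq:
        raise ValueError("empty peptide")
    try:
        residue_sum = sum(_pmass.std_aa_mass[aa] for aa in seq)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in {seq}") from exc
    mono = residue_sum + _WATER + PIC_DELTA
    for state in form.k_states.values():
        mono += STATE_DELTA[state]
    mz = (mono + cfg.charge * PROTON_MASS) / cfg.charge
    return FormMass(mono, mz)


def ppm_match(observed_mz: float, theoretical_mz: float, tol_ppm: float) -> bool:
    """True when the observed m/z is within ``tol_ppm`` of the theoretical."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6 <= tol_ppm


def theoretical_form_table(
    protein: ProteinRecord, cfg: MsConfig = MsConfig()
) -> list[tuple[PeptideSpan, str, float, float]]:
    """(span, form label, mass, m/z) for every form of every digest peptide —
    the inclusion-list table."""
    out = []
    for span in digest_argc(protein, cfg):
        if len(span.k_positions) > cfg.max_modifiable_K:
            continue
        for form in enumerate_forms(span, cfg):
            fm = form_mass(form, cfg)
            out.append((span, form.label, fm.monoisotopic_mass, fm.mz))
    return out


# ---------------------------------------------------------------------------
# identification filtering and quantification

def filter_identifications(
    obs: Sequence[AucObservation], cfg: MsConfig = MsConfig()
) -> list[AucObservation]:
    """Keep observations with search score strictly above 50 and localization
    probability strictly above 0.75 (defaults; both comparisons strict)."""
    return [
        o for o in obs
        if o.andromeda_score > cfg.min_andromeda_score
        and o.localization_prob > cfg.min_localization_prob
    ]


SpanKey = tuple[str, int, int]  # (histone_id, span_start, span_end)


@dataclass(frozen=True)
class QuantResult:
    """%RA per form, grouped by peptide span. Values per span sum to 100."""

    table: Mapping[SpanKey, Mapping[str, float]]

    def spans(self) -> list[SpanKey]:
        return sorted(self.table)

    def ra(self, histone_id: str, start: int, end: int, form_label: str) -> float:
        return self.table[(histone_id, start, end)][form_label]


def relative_abundance(obs: Sequence[AucObservation]) -> QuantResult:
    """Percent relative abundance per observed form.

    %RA(form) = 100 * AUC(form) / sum of AUCs of all observed forms of that
    peptide span. Spans whose AUCs are all zero carry no defined %RA and are
    omitted. Duplicate (span, form) rows are an error.
    """
    groups: dict[SpanKey, dict[str, float]] = {}
    for o in obs:
        key = (o.histone_id, o.span_start, o.span_end)
        forms = groups.setdefault(key, {})
        if o.form_label in forms:
            raise ValueError(
                f"duplicate observation for {key} form {o.form_label!r}"
            )
        forms[o.form_label] = o.auc
    table: dict[SpanKey, dict[str, float]] = {}
    for key, forms in groups.items():
        total = sum(forms.values())
        if total <= 0:
            continue
        table[key] = {label: 100.0 * auc / total for label, auc in forms.items()}
    return QuantResult(table)


# ---------------------------------------------------------------------------
# PTM status

class PtmStatus(enum.Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    SPAN_NOT_OBSERVED = "span_not_observed"


#: modification classes a target may ask about; "me" matches any methyl state
_MOD_CLASS = {
    "pr": {KState.PR},
    "me1": {KState.ME1PR},
    "me2": {KState.ME2},
    "me3": {KState.ME3},
    "me": {KState.ME1PR, KState.ME2, KState.ME3},
    "ac": {KState.AC},
}


def detect_ptm_status(
    quant: QuantResult,
    targets: Sequence[tuple[str, int, str]],
    sequences: Mapping[str, str],
    cfg: MsConfig = MsConfig(),
) -> dict[tuple[str, int, str], PtmStatus]:
    """Classify each (histone, K position, modification class) target.

    DETECTED: some quantified form of a span covering the position carries a
    matching lysine state with %RA > 0. SPAN_NOT_OBSERVED: no form of any
    covering span was quantified at all (the residue was invisible to the
    run). NOT_DETECTED: covering spans were quantified, but never with the
    queried modification.
    """
    report: dict[tuple[str, int, str], PtmStatus] = {}
    for histone_id, pos, mod_class in targets:
        if mod_class not in _MOD_CLASS:
            raise ValueError(f"unknown modification class {mod_class!r}")
        seq = sequences.get(histone_id)
        if seq is None:
            raise KeyError(f"no sequence for histone {histone_id!r}")
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "K":
            raise ValueError(
                f"{histone_id} position {pos} is not a lysine in the sequence"
            )
        wanted = _MOD_CLASS[mod_class]
        covering = [
            (h, s, e) for (h, s, e) in quant.table
            if h == histone_id and s <= pos <= e
        ]
        if not covering:
            report[(histone_id, pos, mod_class)] = PtmStatus.SPAN_NOT_OBSERVED
            continue
        detected = False
        for key in covering:
            for label, ra in quant.table[key].items():
                if ra <= 0:
                    continue
                states = parse_form_label(label, span=(key[1], key[2]))
                if states.get(pos) in wanted:
                    detected = True
        report[(histone_id, pos, mod_class)] = (
            PtmStatus.DETECTED if detected else PtmStatus.NOT_DETECTED
        )
    return report


#: Histone H3 and H4 sequences used as defaults. Histone tails are invariant
#: across Ascomycota at every position quantified here; the constants follow
#: the canonical fungal sequences.
HISTONE_H3 = (
    "ARTKQTARKSTGGKAPRKQLASKAARKSAPSTGGVKKPHRYKPGTVALREIRRFQKSTELLIRKLPFQRLV"
    "REIAQDFKTDLRFQSSAIGALQESVEAYLVSLFEDTNLAAIHAKRVTIQKKDIKLARRLRGERS"
)
HISTONE_H4 = (
    "MSGRGKGGKGLGKGGAKRHRKILRDNIQGITKPAIRRLARRGGVKRISGLIYEEVRAVLKSFLESVIRDSV"
    "TYTEHAKRKTVTSLDVVYALKRQGRTLYGFGG"
)[1:]  # mature H4: initiator methionine removed

DEFAULT_HISTONES = {"H3": HISTONE_H3, "H4": HISTONE_H4}
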