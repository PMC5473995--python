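"""Synthetic cadherin families with full ground truth.

The generator emits cadherin-like proteins from architectural blueprints
(tandem ~85–140 aa EC repeats delimited by planted Ca²⁺-binding DXNDN
linker motifs, then NC / CE / LG / TM / CP membrane-proximal modules with
planted cysteine patterns and an optional C-terminal E-[S/A]-W-C motif),
reverse-translates them into genes with planted GT-AG introns at chosen
(residue, phase) sites, and derives ortholog/paralog families at controlled
divergence with exact residue-level homology maps — so every downstream
pipeline stage can be scored against planted truth without any downloads.

Two deliberate generator guarantees keep the truth exact: background
sequence (and every mutation) is resampled so that DXNDN-class motifs occur
*only* where planted, and cysteines occur only where the cysteine plan puts
them.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align import load_matrix
from .domains import _score_dxndn
from .introns import IntronSite
from .records import (
    DomainAnnotation,
    DomainSegment,
    GeneModel,
    MultipleAlignment,
    NucleotideRecord,
    ProteinRecord,
    ValidationError,
)

#: background alphabet: the 19 standard residues minus cysteine (cysteines
#: appear only where the cysteine plan plants them)
BACKGROUND_AA = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_AA = "LIVFMA"
#: residues that can never contribute to a DXNDN-class motif
_NEUTRAL_AA = "QSTAG"

_EXPECTED_EC = {"III": range(14, 18), "IVa": range(7, 8), "IVb": range(9, 10)}


@dataclass(frozen=True)
class CadherinBlueprint:
    """Architectural plan for one synthetic classical cadherin.

    ``membrane_proximal`` lists the (label, length) modules that follow the
    EC array, in order (NC → … → CP).  ``cys_plan`` entries are
    (segment label, 1-based offset within the segment, pattern class) where
    pattern class is ``solitary``, ``CC`` or ``CXC``.  ``missing_linkers``
    holds junction indices (0 = Nt/EC1 junction, j = EC_j/EC_{j+1} junction,
    n = ECn/NC junction) whose DXNDN motif is left out — a Ca²⁺-free linker.
    ``intron_plan`` is a tuple of (protein position, phase) pairs.
    """

    type_label: str
    ec_lengths: tuple[int, ...]
    membrane_proximal: tuple[tuple[str, int], ...]
    nt_len: int = 90
    cys_plan: tuple[tuple[str, int, str], ...] = ()
    cterm_motif: bool = True
    missing_linkers: frozenset[int] = frozenset()
    intron_plan: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_label not in ("III", "IVa", "IVb", "non_categorized"):
            raise ValidationError(f"unknown type label {self.type_label!r}")
        expected = _EXPECTED_EC.get(self.type_label)
        if expected is not None and len(self.ec_lengths) not in expected:
            raise ValidationError(
                f"type {self.type_label} requires {expected} EC domains, "
                f"blueprint has {len(self.ec_lengths)}"
            )
        for ln in self.ec_lengths:
            if not 85 <= ln <= 140:
                raise ValidationError(f"EC length {ln} outside 85..140")
        seg_lens = dict(self.membrane_proximal)
        for label, off, pat in self.cys_plan:
            span = {"solitary": 1, "CC": 2, "CXC": 3}[pat]
            if label.startswith("EC"):
                idx = int(label[2:]) - 1
                seg_len = self.ec_lengths[idx]
            else:
                seg_len = seg_lens[label]
            if not 6 <= off <= seg_len - span + 1:
                raise ValidationError(
                    f"cysteine plan entry {label}@{off} outside segment"
                )
        L = self.protein_length
        for pos, phase in self.intron_plan:
            if not 1 <= pos <= L:
                raise ValidationError(f"intron position {pos} outside protein")
            if phase not in (0, 1, 2):
                raise ValidationError(f"intron phase {phase} not in 0..2")

    @property
    def protein_length(self) -> int:
        return (
            self.nt_len
            + sum(self.ec_lengths)
            + sum(ln for _, ln in self.membrane_proximal)
        )


def default_blueprint(type_label: str, seed: int = 0,
                      ec_count: int | None = None,
                      ec_len: int = 112) -> CadherinBlueprint:
    """Blueprints mirroring the study architectures.

    Type III defaults to 17 EC repeats and the NC-CE1-LG1-CE2-LG2-CE3-TM-CP
    membrane-proximal block (2985 aa in total, the scale of the spider
    type III proteins); IVa/IVb default to 7/9 ECs with the reduced
    NC-CE1-LG1-TM-CP block, IVa carrying a Ca²⁺-free linker at its EC2/EC3
    junction.  ``ec_count`` overrides the repeat number (the type invariant
    is then relaxed to ``non_categorized`` blueprints only).
    """
    ce_cys = lambda lbl: (  # noqa: E731 - local shorthand
        (lbl, 6, "CC"), (lbl, 16, "CXC"), (lbl, 30, "CC"),
    )
    if type_label == "III":
        n = 17 if ec_count is None else ec_count
        mp = (("NC", 170), ("CE1", 45), ("LG1", 180), ("CE2", 45),
              ("LG2", 180), ("CE3", 45), ("TM", 21), ("CP", 305))
        cys = (("EC1", 40, "solitary"), ("EC1", 70, "solitary"),
               *ce_cys("CE1"), *ce_cys("CE2"), *ce_cys("CE3"))
        nt = 90
    elif type_label in ("IVa", "IVb"):
        n = (7 if type_label == "IVa" else 9) if ec_count is None else ec_count
        mp = (("NC", 160), ("CE1", 45), ("LG1", 180), ("TM", 21), ("CP", 155))
        cys = (("EC1", 40, "solitary"), ("EC1", 70, "solitary"),
               *ce_cys("CE1"))
        nt = 60
    else:
        raise ValueError(f"no default blueprint for {type_label!r}")
    label = type_label
    if ec_count is not None and ec_count not in _EXPECTED_EC[type_label]:
        label = "non_categorized"
    return CadherinBlueprint(
        type_label=label,
        ec_lengths=(ec_len,) * n,
        membrane_proximal=mp,
        nt_len=nt,
        cys_plan=cys,
        missing_linkers=frozenset({2}) if type_label == "IVa" else frozenset(),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted truth accompanying one generated protein (or gene)."""

    annotation: DomainAnnotation
    linker_positions: list[int]
    cys_positions: list[int]
    cterm_motif_span: tuple[int, int] | None = None
    gene_model: GeneModel | None = None
    intron_sites: list[IntronSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Low-level sequence helpers

def _background(rng: np.random.Generator, n: int) -> list[str]:
    return [BACKGROUND_AA[i] for i in rng.integers(0, len(BACKGROUND_AA), n)]


def _sanitize_motifs(chars: list[str], protected: set[int],
                     rng: np.random.Generator) -> None:
    """Resample residues so no DXNDN-class window (score ≥ 4) survives
    outside the protected (planted-motif) spans.  In place; 0-based."""
    i = 0
    n = len(chars)
    while i <= n - 5:
        span = range(i, i + 5)
        if any(p in protected for p in span):
            i += 1
            continue
        if _score_dxndn("".join(chars[i : i + 5])) >= 4:
            for off, req in ((0, "D"), (3, "D"), (4, "N"), (2, "NDE")):
                p = i + off
                if chars[p] in req:
                    chars[p] = _NEUTRAL_AA[rng.integers(0, len(_NEUTRAL_AA))]
                    break
            i = max(0, i - 4)
        else:
            i += 1


def _motif_instance(rng: np.random.Generator) -> list[str]:
    x = BACKGROUND_AA[rng.integers(0, len(BACKGROUND_AA))]
    mid = "NDE"[rng.integers(0, 3)]
    return ["D", x, mid, "D", "N"]


# ---------------------------------------------------------------------------
# Protein generation

def generate_protein(blueprint: CadherinBlueprint,
                     record_id: str = "synthetic",
                     seed: int | None = None
                     ) -> tuple[ProteinRecord, GroundTruth]:
    """Instantiate a blueprint as a concrete protein with planted truth.

    Deterministic under the seed.  The returned annotation records the true
    block boundaries; linker motifs sit at the first five residues of each
    EC block (and of NC), so consecutive motif positions delimit the ECs.
    """
    rng = np.random.default_rng(blueprint.seed if seed is None else seed)
    n_ec = len(blueprint.ec_lengths)
    chars: list[str] = []
    segments: list[DomainSegment] = []
    protected: set[int] = set()  # 0-based indices of planted motifs
    linker_positions: list[int] = []

    def _append(label: str, klass: str, block: list[str]) -> None:
        start = len(chars) + 1
        chars.extend(block)
        segments.append(
            DomainSegment(label=label, klass=klass, start=start,
                          end=len(chars))
        )

    nt = _background(rng, blueprint.nt_len)
    nt[0] = "M"
    _append("Nt", "Nt", nt)
    for i, ln in enumerate(blueprint.ec_lengths, start=1):
        block = _background(rng, ln)
        if (i - 1) not in blueprint.missing_linkers:
            start0 = len(chars)
            block[:5] = _motif_instance(rng)
            protected.update(range(start0, start0 + 5))
            linker_positions.append(start0 + 1)
        _append(f"EC{i}", "EC", block)
    for label, ln in blueprint.membrane_proximal:
        block = _background(rng, ln)
        if label == "NC" and n_ec not in blueprint.missing_linkers:
            start0 = len(chars)
            block[:5] = _motif_instance(rng)
            protected.update(range(start0, start0 + 5))
            linker_positions.append(start0 + 1)
        if label == "TM":
            block = [HYDROPHOBIC_AA[j]
                     for j in rng.integers(0, len(HYDROPHOBIC_AA), ln)]
        klass = label[:2] if label[:2] in ("CE", "LG") else (
            "TM" if label == "TM" else ("CP" if label == "CP" else "NC")
        )
        _append(label, klass, block)

    # plant cysteines
    seg_start = {s.label: s.start for s in segments}
    cys_positions: list[int] = []
    for label, off, pat in blueprint.cys_plan:
        base = seg_start[label] + off - 1  # 1-based
        offsets = {"solitary": (0,), "CC": (0, 1), "CXC": (0, 2)}[pat]
        for d in offsets:
            chars[base - 1 + d] = "C"
            cys_positions.append(base + d)
        if pat == "CXC" and chars[base] == "C":
            chars[base] = _NEUTRAL_AA[rng.integers(0, len(_NEUTRAL_AA))]
        protected.update(base - 1 + d for d in range(max(offsets) + 1))
    cys_positions.sort()

    cterm_span = None
    if blueprint.cterm_motif:
        L = len(chars)
        chars[L - 4 : L] = ["E", "SA"[rng.integers(0, 2)], "W", "C"]
        protected.update(range(L - 4, L))
        cterm_span = (L - 3, L)
        cys_positions.append(L)

    _sanitize_motifs(chars, protected, rng)
    record = ProteinRecord(id=record_id, sequence="".join(chars))
    annotation = DomainAnnotation(record_id=record_id, segments=segments)
    return record, GroundTruth(
        annotation=annotation,
        linker_positions=linker_positions,
        cys_positions=sorted(set(cys_positions)),
        cterm_motif_span=cterm_span,
    )


def preserved_positions(truth: GroundTruth,
                        preserve: tuple[str, ...] = ("linkers", "cysteines",
                                                     "motifs", "tm")) -> set[int]:
    """1-based positions mutation must leave untouched.

    The transmembrane span is preserved by default: its hydrophobicity is
    under purifying selection just like the Ca²⁺-binding linkers, and a
    degraded anchor would not be the architecture the blueprint planted.
    """
    keep: set[int] = set()
    if "linkers" in preserve:
        for p in truth.linker_positions:
            keep.update(range(p, p + 5))
    if "cysteines" in preserve:
        keep.update(truth.cys_positions)
    if "motifs" in preserve and truth.cterm_motif_span:
        s, e = truth.cterm_motif_span
        keep.update(range(s, e + 1))
    if "tm" in preserve:
        for seg in truth.annotation.segments:
            if seg.klass == "TM":
                keep.update(range(seg.start, seg.end + 1))
    return keep


# ---------------------------------------------------------------------------
# Gene construction (reverse translation + planted GT-AG introns)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(_TABLE.stop_codons)

_NT = "ACGT"

#: planted introns are kept at least this many codons apart so that splice
#: inference always has a clean 20-nt exact-match seed inside each exon
MIN_SITE_SPACING_CODONS = 10


def _random_nt(rng: np.random.Generator, n: int, forbid_atg: bool = False) -> str:
    while True:
        s = "".join(_NT[i] for i in rng.integers(0, 4, n))
        if not (forbid_atg and "ATG" in s):
            return s


def build_gene(protein: ProteinRecord | str, intron_plan,
               seed: int, gene_id: str | None = None, utr5_len: int = 50,
               utr3_len: int = 50, intron_len_range: tuple[int, int] = (60, 200)
               ) -> tuple[NucleotideRecord, NucleotideRecord, GeneModel,
                          list[IntronSite]]:
    """Reverse-translate a protein and plant GT-AG introns.

    ``intron_plan`` is a sequence of (protein position, phase) pairs; the
    intron is inserted after ``3·(position−1) + phase`` coding bases.  The
    spliced CDS translates back to the protein exactly; every intron begins
    GT and ends AG and is at least 60 nt long.
    """
    if isinstance(protein, ProteinRecord):
        aa_seq, pid = protein.sequence, protein.id
    else:
        aa_seq, pid = protein, "synthetic"
    gene_id = gene_id or pid
    rng = np.random.default_rng(seed)
    if "X" in aa_seq:
        raise ValidationError("cannot reverse-translate unknown residues")
    cds = "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in aa_seq
    ) + _STOPS[rng.integers(0, len(_STOPS))]
    utr5 = _random_nt(rng, utr5_len, forbid_atg=True)
    utr3 = _random_nt(rng, utr3_len)
    transcript_seq = utr5 + cds + utr3

    plan = sorted(intron_plan)
    offsets = []
    for pos, phase in plan:
        coding_offset = 3 * (pos - 1) + phase
        if not 0 < coding_offset < len(cds):
            raise ValidationError(
                f"intron at ({pos},{phase}) outside the coding region"
            )
        offsets.append(utr5_len + coding_offset)
    if any(b - a < 3 * MIN_SITE_SPACING_CODONS
           for a, b in zip(offsets, offsets[1:])):
        raise ValidationError(
            f"planted introns closer than {MIN_SITE_SPACING_CODONS} codons"
        )

    lo, hi = intron_len_range
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    sites: list[IntronSite] = []
    prev_t = 0  # transcript cursor
    g_cursor = 0  # genomic length so far
    for off, (pos, phase) in zip(offsets, plan):
        exon_seq = transcript_seq[prev_t:off]
        exons.append((g_cursor + 1, g_cursor + len(exon_seq)))
        pieces.append(exon_seq)
        g_cursor += len(exon_seq)
        ilen = int(rng.integers(lo, hi + 1))
        intron = "GT" + _random_nt(rng, ilen - 4) + "AG"
        sites.append(
            IntronSite(gene_id=gene_id, protein_position=pos, phase=phase,
                       genomic_donor=g_cursor + 1,
                       genomic_acceptor=g_cursor + ilen)
        )
        pieces.append(intron)
        g_cursor += ilen
        prev_t = off
    exon_seq = transcript_seq[prev_t:]
    exons.append((g_cursor + 1, g_cursor + len(exon_seq)))
    pieces.append(exon_seq)

    genomic = NucleotideRecord(id=f"{gene_id}_genomic", sequence="".join(pieces),
                               kind="genomic")
    transcript = NucleotideRecord(id=gene_id, sequence=transcript_seq,
                                  kind="transcript")
    model = GeneModel(gene_id=gene_id, seq_id=genomic.id, strand="+",
                      exons=exons, cds_start_offset=utr5_len,
                      cds_length=len(cds))
    assert model.spliced_sequence(genomic) == transcript_seq
    assert str(Seq(cds).translate()) == aa_seq + "*"
    return genomic, transcript, model, sites


# ---------------------------------------------------------------------------
# Ortholog / paralog derivation

_SUB_WEIGHTS: dict[str, np.ndarray] = {}


def _substitution_weights(aa: str) -> np.ndarray:
    """BLOSUM62-biased replacement distribution over BACKGROUND_AA \\ {aa}."""
    if aa not in _SUB_WEIGHTS:
        m = load_matrix("BLOSUM62")
        w = np.array(
            [
                0.0 if b == aa else float(np.exp(m[aa, b] / 2.0))
                for b in BACKGROUND_AA
            ]
        )
        _SUB_WEIGHTS[aa] = w / w.sum()
    return _SUB_WEIGHTS[aa]


def derive_variant(protein: ProteinRecord, target_divergence: float,
                   seed: int, new_id: str,
                   preserve: set[int] | None = None,
                   delete_spans: list[tuple[int, int]] | None = None,
                   protect_from_indels: set[int] | None = None,
                   indel_rate: float = 1 / 500.0, indel_mean: float = 3.0
                   ) -> tuple[ProteinRecord, dict[int, int]]:
    """Derive a variant by block deletions, substitutions, and rare indels.

    ``target_divergence`` is the fraction of retained positions substituted
    (BLOSUM-biased, never creating cysteines or DXNDN-class motifs);
    ``preserve`` positions (1-based, on the parent) are never substituted,
    deleted, or disrupted; ``protect_from_indels`` positions may be
    substituted but not removed.  Returns the variant and the child→parent
    residue homology map (both 1-based).
    """
    if not 0 <= target_divergence < 0.9:
        raise ValidationError("target divergence must be in [0, 0.9)")
    rng = np.random.default_rng(seed)
    preserve = set(preserve) if preserve else set()
    if protein.sequence[0] == "M":
        preserve.add(1)  # orthologs keep their initiator methionine
    protect = (protect_from_indels or set()) | preserve
    entries: list[tuple[int | None, str]] = [
        (i + 1, ch) for i, ch in enumerate(protein.sequence)
    ]
    if delete_spans:
        drop: set[int] = set()
        for s, e in delete_spans:
            drop.update(range(s, e + 1))
        entries = [(p, ch) for p, ch in entries if p not in drop]
        preserve = preserve - drop  # landmarks inside a deleted block go too

    eligible = [k for k, (p, _) in enumerate(entries) if p not in preserve]
    n_sub = round(target_divergence * len(entries))
    if n_sub > len(eligible):
        raise ValidationError(
            "target divergence unreachable with preserved landmarks"
        )
    order = rng.permutation(len(eligible))
    for k in order[:n_sub]:
        idx = eligible[k]
        p, ch = entries[idx]
        w = _substitution_weights(ch)
        entries[idx] = (p, BACKGROUND_AA[rng.choice(len(BACKGROUND_AA), p=w)])

    n_indel = int(rng.binomial(n_sub, indel_rate)) if n_sub else 0
    for _ in range(n_indel):
        length = int(min(rng.geometric(1.0 / indel_mean), 10))
        if rng.integers(0, 2) == 0 and len(entries) > length + 10:
            # deletion of a run free of protected positions
            for _try in range(50):
                s = int(rng.integers(1, len(entries) - length))
                run = entries[s : s + length]
                if all(p is None or p not in protect for p, _ in run):
                    del entries[s : s + length]
                    break
        else:
            s = int(rng.integers(1, len(entries)))
            entries[s:s] = [(None, c) for c in _background(rng, length)]

    _sanitize_novel_motifs(entries, protein.sequence, preserve, rng)
    homology = {
        k + 1: p for k, (p, _) in enumerate(entries) if p is not None
    }
    child = ProteinRecord(id=new_id, sequence="".join(ch for _, ch in entries),
                          taxon=protein.taxon, group=protein.group)
    return child, homology


def _sanitize_novel_motifs(entries: list[tuple[int | None, str]],
                           parent_seq: str, preserve: set[int],
                           rng: np.random.Generator) -> None:
    """Resample residues so mutation never *creates* a DXNDN-class window.

    A window inherited unchanged from the parent (five consecutive parent
    positions, identical residues) passes through — the parent's own
    surviving motifs are planted truth.  Any other window scoring ≥ 4 is
    neutralized at a non-preserved contributing position.  In place.
    """

    def inherited(k: int) -> bool:
        run = entries[k : k + 5]
        ps = [p for p, _ in run]
        if any(p is None for p in ps):
            return False
        if any(ps[d + 1] != ps[d] + 1 for d in range(4)):
            return False
        return all(ch == parent_seq[p - 1] for p, ch in run)

    i = 0
    while i <= len(entries) - 5:
        window = "".join(ch for _, ch in entries[i : i + 5])
        if _score_dxndn(window) >= 4 and not inherited(i):
            fixed = False
            for off, req in ((0, "D"), (3, "D"), (4, "N"), (2, "NDE")):
                p, ch = entries[i + off]
                if ch in req and (p is None or p not in preserve):
                    entries[i + off] = (
                        p, _NEUTRAL_AA[rng.integers(0, len(_NEUTRAL_AA))]
                    )
                    fixed = True
                    break
            i = max(0, i - 4) if fixed else i + 1
        else:
            i += 1


def mutate_ortholog(protein: ProteinRecord, target_divergence: float,
                    seed: int, new_id: str | None = None,
                    preserve: set[int] | None = None,
                    **kwargs) -> tuple[ProteinRecord, dict[int, int]]:
    """Point-substitution/indel ortholog of a protein (no block deletions)."""
    return derive_variant(
        protein, target_divergence, seed,
        new_id=new_id or f"{protein.id}_ortholog",
        preserve=preserve, delete_spans=None, **kwargs,
    )


# ---------------------------------------------------------------------------
# Families

@dataclass
class GeneSpec:
    """One family member: its architecture, taxon group, and divergence."""

    name: str
    group: str  # taxon-group label (drives conservation classifiers)
    type_label: str = "III"  # III keeps the parent; IVa/IVb delete blocks
    divergence: float = 0.25
    n_unique_sites: int = 0
    cys_losses: tuple[int, ...] = ()  # parent positions of planted C to drop


@dataclass
class SitePlan:
    """One planted intron site: its carriers and (optional) fixed placement."""

    carriers: tuple[str, ...] | str = "all"
    parent_position: int | None = None
    phase: int | None = None


@dataclass
class FamilyConfig:
    genes: list[GeneSpec]
    sites: list[SitePlan] = field(default_factory=list)
    parent_ec_count: int = 17
    indel_rate: float = 1 / 500.0


@dataclass
class FamilySim:
    """A generated family plus every planted truth table."""

    parent: ProteinRecord
    parent_truth: GroundTruth
    records: list[ProteinRecord]
    homologies: dict[str, dict[int, int]]  # gene -> child_pos -> parent_pos
    alignment: MultipleAlignment  # true alignment of the family members
    column_of_parent: dict[int, int]  # parent residue -> alignment column
    groups: dict[str, str]
    genomics: dict[str, NucleotideRecord]
    transcripts: dict[str, NucleotideRecord]
    gene_models: dict[str, GeneModel]
    intron_truth: dict[str, list[IntronSite]]
    site_plans: list[dict]  # parent_position, phase, carriers, column
    cys_truth: dict[int, list[str]]  # alignment column -> genes carrying C


def _deletion_spans(truth: GroundTruth, type_label: str,
                    n_parent_ec: int) -> list[tuple[int, int]]:
    """Parent blocks removed to derive a type IVa/IVb architecture.

    IVb keeps parent EC6–EC14 (9 repeats, the two extra N-terminal ones
    primitive); IVa keeps EC8–EC14 (7 repeats); both lose CE2, LG2 and CE3.
    """
    if type_label == "III":
        return []
    if n_parent_ec < 14:
        raise ValidationError(
            "type IV derivation needs a parent with at least 14 EC repeats"
        )
    segs = {s.label: s for s in truth.annotation.segments}
    first_kept = {"IVb": 6, "IVa": 8}[type_label]
    spans = [(segs["EC1"].start, segs[f"EC{first_kept - 1}"].end)]
    if n_parent_ec > 14:
        spans.append((segs["EC15"].start, segs[f"EC{n_parent_ec}"].end))
    spans.append((segs["CE2"].start, segs["CE3"].end))
    return spans


def _retained(truth: GroundTruth, type_label: str, n_parent_ec: int,
              parent_len: int) -> set[int]:
    drop: set[int] = set()
    for s, e in _deletion_spans(truth, type_label, n_parent_ec):
        drop.update(range(s, e + 1))
    return set(range(1, parent_len + 1)) - drop


def generate_family(config: FamilyConfig, seed: int) -> FamilySim:
    """Generate a full fixture: proteins, genes, alignment, truth tables."""
    rng = np.random.default_rng(seed)
    parent_bp = default_blueprint("III", seed=int(rng.integers(2**31 - 1)),
                                  ec_count=config.parent_ec_count)
    parent, truth = generate_protein(parent_bp, record_id="parent")
    n_ec = config.parent_ec_count
    keep = preserved_positions(truth)
    parent_len = len(parent.sequence)

    retained = {
        spec.name: _retained(truth, spec.type_label, n_ec, parent_len)
        for spec in config.genes
    }

    # resolve intron-site plans on parent coordinates.  Spacing is enforced
    # both on the parent and in every carrier's post-deletion coordinates
    # (a block deletion can bring two parent positions much closer), with
    # enough slack that the indel-exclusion margin around each site keeps
    # child-space spacing above build_gene's minimum.
    import bisect

    names = [spec.name for spec in config.genes]
    resolved: list[dict] = []
    used_codons: set[int] = set()
    retained_sorted = {name: sorted(retained[name]) for name in names}
    used_by_gene: dict[str, list[int]] = {name: [] for name in names}
    SPACING = 25  # codons; > 2 * INDEL_MARGIN + MIN_SITE_SPACING_CODONS
    INDEL_MARGIN = 7

    def _spacing_ok(pos: int, carriers: list[str]) -> bool:
        if any(abs(pos - u) < SPACING for u in used_codons):
            return False
        for g in carriers:
            rs = retained_sorted[g]
            r = bisect.bisect_left(rs, pos)
            for u in used_by_gene[g]:
                if abs(r - bisect.bisect_left(rs, u)) < SPACING:
                    return False
        return True

    def _place(plan_carriers: list[str], fixed_pos: int | None,
               fixed_phase: int | None) -> None:
        common = set.intersection(*(retained[c] for c in plan_carriers))
        common -= keep  # keep planted landmarks clean of intron bookkeeping
        if fixed_pos is not None:
            pos = fixed_pos
            for c in plan_carriers:
                if pos not in retained[c]:
                    raise ValidationError(
                        f"intron site at parent position {pos} planted in "
                        f"gene {c!r} lacking that residue"
                    )
        else:
            cands = sorted(
                p for p in common
                if 30 < p < parent_len - 30 and _spacing_ok(p, plan_carriers)
            )
            if not cands:
                raise ValidationError("no placement left for an intron site")
            pos = int(cands[int(rng.integers(0, len(cands)))])
        phase = int(rng.integers(0, 3)) if fixed_phase is None else fixed_phase
        used_codons.add(pos)
        for g in plan_carriers:
            used_by_gene[g].append(pos)
        resolved.append({"parent_position": pos, "phase": phase,
                         "carriers": plan_carriers})

    for plan in config.sites:
        carriers = names if plan.carriers == "all" else list(plan.carriers)
        unknown = set(carriers) - set(names)
        if unknown:
            raise ValidationError(f"unknown site carriers {sorted(unknown)}")
        _place(carriers, plan.parent_position, plan.phase)

    for spec in config.genes:
        for _ in range(spec.n_unique_sites):
            _place([spec.name], None, None)

    # indels may never come near a planted site codon, so child-space site
    # spacing cannot shrink below the splice-inference minimum
    protect = {
        q for p in used_codons
        for q in range(p - INDEL_MARGIN, p + INDEL_MARGIN + 1)
    }

    # derive the children
    records: list[ProteinRecord] = []
    homologies: dict[str, dict[int, int]] = {}
    groups: dict[str, str] = {}
    genomics, transcripts, models, intron_truth = {}, {}, {}, {}
    for spec in config.genes:
        child, hom = derive_variant(
            parent, spec.divergence, seed=int(rng.integers(2**31 - 1)),
            new_id=spec.name, preserve=keep,
            delete_spans=_deletion_spans(truth, spec.type_label, n_ec),
            protect_from_indels=protect, indel_rate=config.indel_rate,
        )
        parent_to_child = {p: c for c, p in hom.items()}
        if spec.cys_losses:
            chars = list(child.sequence)
            for p in spec.cys_losses:
                if p not in truth.cys_positions:
                    raise ValidationError(
                        f"{spec.name}: cysteine loss at {p} not a planted C"
                    )
                c = parent_to_child.get(p)
                if c is None:
                    raise ValidationError(
                        f"{spec.name}: cysteine loss at deleted position {p}"
                    )
                chars[c - 1] = "S"
            child = ProteinRecord(id=child.id, sequence="".join(chars))
        records.append(child)
        homologies[spec.name] = hom
        groups[spec.name] = spec.group

        plan = []
        for site in resolved:
            if spec.name in site["carriers"]:
                c = parent_to_child.get(site["parent_position"])
                if c is None:
                    raise ValidationError(
                        f"{spec.name}: lost planted intron site "
                        f"{site['parent_position']}"
                    )
                plan.append((c, site["phase"]))
        g, t, m, s = build_gene(child, plan,
                                seed=int(rng.integers(2**31 - 1)),
                                gene_id=spec.name)
        genomics[spec.name], transcripts[spec.name] = g, t
        models[spec.name], intron_truth[spec.name] = m, s

    alignment, col_of_parent = true_alignment(parent, records, homologies)
    for site in resolved:
        site["column"] = col_of_parent[site["parent_position"]]

    cys_truth: dict[int, list[str]] = {}
    lost = {spec.name: set(spec.cys_losses) for spec in config.genes}
    for p in truth.cys_positions:
        carriers = [
            spec.name for spec in config.genes
            if p in retained[spec.name] and p not in lost[spec.name]
        ]
        if carriers:
            cys_truth[col_of_parent[p]] = carriers

    return FamilySim(
        parent=parent, parent_truth=truth, records=records,
        homologies=homologies, alignment=alignment,
        column_of_parent=col_of_parent, groups=groups,
        genomics=genomics, transcripts=transcripts, gene_models=models,
        intron_truth=intron_truth, site_plans=resolved, cys_truth=cys_truth,
    )


def true_alignment(parent: ProteinRecord, records: list[ProteinRecord],
                   homologies: dict[str, dict[int, int]]
                   ) -> tuple[MultipleAlignment, dict[int, int]]:
    """Exact multiple alignment implied by the child→parent homology maps.

    Parent positions scaffold the columns; child-specific insertions get
    extra left-aligned columns after their anchor position.
    """
    Lp = len(parent.sequence)
    matched: dict[str, dict[int, str]] = {}
    inserts: dict[str, dict[int, list[str]]] = {}
    for rec in records:
        hom = homologies[rec.id]
        matched[rec.id] = {}
        inserts[rec.id] = {}
        last_p = 0
        for c in range(1, len(rec.sequence) + 1):
            p = hom.get(c)
            ch = rec.sequence[c - 1]
            if p is not None:
                matched[rec.id][p] = ch
                last_p = p
            else:
                inserts[rec.id].setdefault(last_p, []).append(ch)
    ins_width = {
        p: max((len(inserts[r.id].get(p, [])) for r in records), default=0)
        for p in range(0, Lp + 1)
    }
    rows = []
    col_of_parent: dict[int, int] = {}
    # compute column of each parent position once
    col = 0
    for p in range(0, Lp + 1):
        col += ins_width[p]
        if p < Lp:
            col += 1
            col_of_parent[p + 1] = col
    for rec in records:
        parts: list[str] = []
        for p in range(0, Lp + 1):
            ins = inserts[rec.id].get(p, [])
            parts.append("".join(ins) + "-" * (ins_width[p] - len(ins)))
            if p < Lp:
                parts.append(matched[rec.id].get(p + 1, "-"))
        rows.append((rec.id, "".join(parts)))
    return MultipleAlignment(rows=rows), col_of_parent


# ---------------------------------------------------------------------------
# Ready-made scenarios

def planted_deletion_pair(seed: int, deletion_length: int = 240,
                          ec_count: int = 9
                          ) -> tuple[ProteinRecord, ProteinRecord, int]:
    """A parent and a child with one internal block deletion (no point
    mutations): the planted-gap scenario for dot-plot chaining.

    Returns (parent, child, deletion start on the parent, 1-based).
    """
    rng = np.random.default_rng(seed)
    bp = default_blueprint("III", seed=int(rng.integers(2**31 - 1)),
                           ec_count=ec_count)
    parent, _truth = generate_protein(bp, record_id="parent")
    L = len(parent.sequence)
    start = int(rng.integers(300, L - deletion_length - 400))
    child, _hom = derive_variant(
        parent, 0.0, seed=int(rng.integers(2**31 - 1)), new_id="deleted",
        delete_spans=[(start, start + deletion_length - 1)],
    )
    return parent, child, start


def cysteine_loss_scenario(seed: int) -> tuple[FamilySim, list[int]]:
    """A family where one lineage lost two otherwise-stable cysteines.

    Returns the simulated family and the true alignment columns of the two
    lost cysteines (expected ``lineage_loss`` calls).
    """
    rng = np.random.default_rng(seed)
    probe_bp = default_blueprint("III", seed=0, ec_count=14)
    _, probe_truth = generate_protein(probe_bp, record_id="probe")
    ec1 = next(s for s in probe_truth.annotation.segments if s.label == "EC1")
    losses = tuple(
        p for p in probe_truth.cys_positions if ec1.start <= p <= ec1.end
    )
    assert len(losses) == 2
    genes = [
        GeneSpec(name=f"spider{i}", group="chelicerate", divergence=0.18)
        for i in (1, 2)
    ] + [
        GeneSpec(name=f"insect{i}", group="insect", divergence=0.25,
                 cys_losses=losses)
        for i in (1, 2, 3)
    ] + [
        GeneSpec(name=f"crust{i}", group="crustacean", divergence=0.25)
        for i in (1, 2, 3)
    ]
    sim = generate_family(
        FamilyConfig(genes=genes, parent_ec_count=14), seed=int(rng.integers(2**31 - 1))
    )
    loss_columns = [sim.column_of_parent[p] for p in losses]
    return sim, loss_columns
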