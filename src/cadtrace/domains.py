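"""Domain segmentation and type classification of classical cadherins.

A classical cadherin is segmented into an optional N-terminal region (Nt), a
tandem array of extracellular cadherin repeats (EC1..ECn) delimited by
Ca²⁺-binding linker motifs, a membrane-proximal block (NC, then cysteine-rich
EGF-like CE domains interleaved with laminin-globular LG domains), a
transmembrane helix (TM) and the cytoplasmic tail (CP).  The protein is then
classified as type III (14–17 ECs with the full NC-CE1-LG1-CE2-LG2-CE3
block), type IVa (7 ECs, no CE2/LG2/CE3), type IVb (9 ECs, no CE2/LG2/CE3)
or non-categorized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentParams, PairwiseAlignment, global_align
from .records import (
    ColumnMap,
    DomainAnnotation,
    DomainSegment,
    ProteinRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

MOTIF_CLASSES = ("DXD", "DXNDN", "XPXF")


@dataclass(frozen=True)
class LinkerMotifHit:
    """A Ca²⁺-binding (or XPXF landmark) motif occurrence.

    ``score`` counts satisfied template positions; for DXNDN a hit needs at
    least 4 of the 5 positions (the wildcard always counts).
    """

    position: int  # 1-based start
    motif_class: str
    score: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("motif position must be >= 1")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValidationError(f"unknown motif class {self.motif_class!r}")


_MOTIF_SPANS = {"DXD": 3, "DXNDN": 5, "XPXF": 4}


def _score_dxndn(w: str) -> int:
    # template D-x-[NDE]-D-N; 'X' (unknown residue) never matches a motif
    if "X" in w:
        return 0
    return (
        (w[0] == "D")
        + 1  # wildcard position
        + (w[2] in "NDE")
        + (w[3] == "D")
        + (w[4] == "N")
    )


def scan_linker_motifs(protein: ProteinRecord | str,
                       min_dxndn_score: int = 4) -> list[LinkerMotifHit]:
    """All DXD / DXNDN / XPXF motif occurrences, sorted by position.

    Overlapping hits of the same class are collapsed to the best-scoring
    (ties: most N-terminal) one.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    raw: list[LinkerMotifHit] = []
    n = len(seq)
    for i in range(n - 4):
        s = _score_dxndn(seq[i : i + 5])
        if s >= min_dxndn_score:
            raw.append(LinkerMotifHit(position=i + 1, motif_class="DXNDN", score=s))
    for i in range(n - 2):
        w = seq[i : i + 3]
        if "X" not in w and w[0] == "D" and w[2] == "D":
            raw.append(LinkerMotifHit(position=i + 1, motif_class="DXD", score=3))
    for i in range(n - 3):
        w = seq[i : i + 4]
        if "X" not in w and w[1] == "P" and w[3] == "F":
            raw.append(LinkerMotifHit(position=i + 1, motif_class="XPXF", score=4))
    # collapse overlapping same-class hits
    out: list[LinkerMotifHit] = []
    for klass in MOTIF_CLASSES:
        span = _MOTIF_SPANS[klass]
        group: list[LinkerMotifHit] = []
        for hit in [h for h in raw if h.motif_class == klass]:
            if group and hit.position < group[-1].position + span:
                group.append(hit)
            else:
                if group:
                    out.append(max(group, key=lambda h: (h.score, -h.position)))
                group = [hit]
        if group:
            out.append(max(group, key=lambda h: (h.score, -h.position)))
    return sorted(out, key=lambda h: (h.position, h.motif_class))


# ---------------------------------------------------------------------------
# EC segmentation

def segment_ec_domains(protein: ProteinRecord | str,
                       linker_hits: list[LinkerMotifHit],
                       min_ec_len: int = 85, max_ec_len: int = 140,
                       max_bridge: int = 2) -> list[DomainSegment]:
    """Delimit EC repeats from consecutive DXNDN-class linker motifs.

    A chain of motif hits is selected by dynamic programming so that each
    chosen consecutive pair is spaced within [min_ec_len, max_ec_len] and the
    number of delimited ECs (then the total motif score) is maximal;
    degenerate spurious motif hits inside a repeat are thereby skipped.
    Afterwards, an unsegmented span *between two called ECs* whose length is
    within k×[min_ec_len, max_ec_len] (k ≤ ``max_bridge``) is bridged into k
    evenly split ECs — this recovers repeats whose junction lacks a
    Ca²⁺-binding motif (Ca²⁺-free linkers).  Two stray motifs with nothing
    called around them are never bridged.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    dxndn = sorted(
        (h for h in linker_hits if h.motif_class == "DXNDN"),
        key=lambda h: h.position,
    )
    if len(dxndn) < 2:
        log.warning("no resolvable EC domains (fewer than 2 linker motifs)")
        return []
    pos = [h.position for h in dxndn]
    sc = [h.score for h in dxndn]
    n = len(pos)
    # f[i] = best (ec_count, motif_score) over chains ending at hit i
    NEG = (-1, -1.0)
    f: list[tuple[int, float]] = [(0, float(sc[i])) for i in range(n)]
    prev: list[int] = [-1] * n
    for i in range(n):
        for j in range(i):
            d = pos[i] - pos[j]
            if min_ec_len <= d <= max_ec_len:
                cand = (f[j][0] + 1, f[j][1] + sc[i])
            else:
                cand = (f[j][0], f[j][1] + sc[i]) if f[j][0] > 0 else NEG
            if cand > f[i]:
                f[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: f[i])
    if f[end][0] == 0:
        log.warning("no resolvable EC domains (no linker pair within bounds)")
        return []
    chain: list[int] = []
    i = end
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()

    # materialize ECs from consecutive chain hits spaced within bounds, and
    # bridge spans where intermediate chain hits were skip steps
    boundaries: list[int] = [pos[i] for i in chain]
    ec_bounds: list[tuple[int, int]] = []  # (start, end) 1-based inclusive
    for a, b in zip(boundaries, boundaries[1:]):
        d = b - a
        if min_ec_len <= d <= max_ec_len:
            ec_bounds.append((a, b - 1))
    # bridging pass over gaps between consecutive called ECs
    bridged: list[tuple[int, int]] = []
    for k in range(len(ec_bounds)):
        bridged.append(ec_bounds[k])
        if k + 1 < len(ec_bounds):
            gap_start = ec_bounds[k][1] + 1
            gap_end = ec_bounds[k + 1][0] - 1
            g = gap_end - gap_start + 1
            if g <= 0:
                continue
            for kk in range(1, max_bridge + 1):
                if min_ec_len <= g / kk <= max_ec_len:
                    cuts = [
                        gap_start + round(t * g / kk) for t in range(kk + 1)
                    ]
                    for t in range(kk):
                        bridged.append((cuts[t], cuts[t + 1] - 1))
                    break
    bridged.sort()
    return [
        DomainSegment(label=f"EC{i}", klass="EC", start=s, end=e)
        for i, (s, e) in enumerate(bridged, start=1)
    ]


# ---------------------------------------------------------------------------
# Membrane anchor

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def detect_membrane_anchor(protein: ProteinRecord | str,
                           min_width: int = 19, max_width: int = 23,
                           threshold: float = 1.6
                           ) -> tuple[DomainSegment | None, DomainSegment | None]:
    """Locate the TM helix as the best mean-hydropathy window in the
    C-terminal half; CP is everything C-terminal of it.

    Returns ``(None, None)`` when no window exceeds the threshold.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    L = len(seq)
    if L < 60:
        raise ValidationError("protein too short for membrane-anchor detection")
    kd = [KYTE_DOOLITTLE[ch] for ch in seq]
    half = L // 2
    best: tuple[float, int, int] | None = None  # (mean, start0, width)
    for width in range(min_width, max_width + 1):
        for s in range(half, L - width + 1):
            mean = sum(kd[s : s + width]) / width
            if mean > threshold and (best is None or mean > best[0] + 1e-12):
                best = (mean, s, width)
    if best is None:
        return None, None
    _, s, width = best
    tm = DomainSegment(label="TM", klass="TM", start=s + 1, end=s + width)
    cp = None
    if tm.end < L:
        cp = DomainSegment(label="CP", klass="CP", start=tm.end + 1, end=L)
    return tm, cp


# ---------------------------------------------------------------------------
# Membrane-proximal CE / LG detection (de novo)

def _cys_clusters(seq: str, start: int, end: int, min_cys: int = 5,
                  span: int = 40) -> list[tuple[int, int]]:
    """Maximal cysteine clusters (>= min_cys C within `span` aa) in a region.

    Coordinates 1-based inclusive within the whole protein.
    """
    cys = [i + 1 for i in range(start - 1, end) if seq[i] == "C"]
    clusters: list[list[int]] = []
    for c in cys:
        if clusters and c - clusters[-1][0] < span:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    # merge adjacent clusters closer than span apart is handled by the chain
    out = []
    for cl in clusters:
        if len(cl) >= min_cys:
            out.append((cl[0], cl[-1]))
    return out


def detect_membrane_proximal(seq: str, ec_end: int, tm_start: int,
                             lg_min: int = 150, lg_max: int = 210
                             ) -> list[DomainSegment]:
    """De novo NC / CE / LG calls between the last EC and the TM.

    CE domains are cysteine clusters (≥5 C within 40 aa); LG domains are
    150–210 aa spans between consecutive CEs or between the last CE and the
    TM.  NC is everything from the EC array end to the first CE.
    """
    segments: list[DomainSegment] = []
    region_start, region_end = ec_end + 1, tm_start - 1
    if region_end <= region_start:
        return segments
    ces = _cys_clusters(seq, region_start, region_end)
    if not ces:
        segments.append(
            DomainSegment(label="NC", klass="NC", start=region_start,
                          end=region_end)
        )
        return segments
    first_ce_start = ces[0][0]
    if first_ce_start > region_start:
        segments.append(
            DomainSegment(label="NC", klass="NC", start=region_start,
                          end=first_ce_start - 1)
        )
    lg_i = 0
    for k, (cs, ce_) in enumerate(ces, start=1):
        segments.append(DomainSegment(label=f"CE{k}", klass="CE", start=cs, end=ce_))
        nxt = ces[k][0] - 1 if k < len(ces) else region_end
        span = nxt - ce_
        if lg_min <= span <= lg_max:
            lg_i += 1
            segments.append(
                DomainSegment(label=f"LG{lg_i}", klass="LG", start=ce_ + 1, end=nxt)
            )
    return segments


# ---------------------------------------------------------------------------
# Reference transfer

def transfer_domains(reference: DomainAnnotation,
                     alignment: PairwiseAlignment) -> DomainAnnotation:
    """Project a reference annotation onto the query through a pairwise
    alignment (row a = reference, row b = query).

    Each reference segment maps to the query residues aligned within its
    columns; a segment entirely absorbed by gaps in the query is absent from
    the output.
    """
    ref_map = ColumnMap(alignment.a_gapped)
    qry_map = ColumnMap(alignment.b_gapped)
    qry_res_at: list[int | None] = [None] * (len(alignment.b_gapped) + 1)
    for col in range(1, len(alignment.b_gapped) + 1):
        qry_res_at[col] = qry_map.residue_of(col)
    segments: list[DomainSegment] = []
    prev_end = 0
    for seg in reference.segments:
        col_s = ref_map.column_of(seg.start)
        col_e = ref_map.column_of(seg.end)
        q_res = [qry_res_at[c] for c in range(col_s, col_e + 1)
                 if qry_res_at[c] is not None]
        if not q_res:
            continue  # absorbed by a deletion in the query
        start, end = max(q_res[0], prev_end + 1), q_res[-1]
        if start > end:
            continue
        segments.append(
            DomainSegment(label=seg.label, klass=seg.klass, start=start, end=end)
        )
        prev_end = end
    # renumber the ECs that survived so indices stay strictly increasing
    ec_numbers = {
        s.label: int(s.label[2:]) for s in segments if s.klass == "EC"
    }
    return DomainAnnotation(record_id="query", segments=segments,
                            ec_numbers=ec_numbers)


# ---------------------------------------------------------------------------
# Classification

@dataclass
class CadherinTypeCall:
    record_id: str
    type: str  # one of records.CADHERIN_TYPES
    ec_count: int
    has_CE2_LG2_CE3: bool
    evidence: list[str] = field(default_factory=list)


def classify_cadherin(annotation: DomainAnnotation) -> CadherinTypeCall:
    """Type III / IVa / IVb / non-categorized call from an annotation.

    Rules, in order: the full CE2+LG2+CE3 block present → type III when the
    EC count is 14–17, otherwise non-categorized; the block absent → IVa for
    exactly 7 ECs, IVb for exactly 9; anything else (including the undefined
    8-EC case) → non-categorized.
    """
    ec_count = annotation.ec_count
    has_block = all(annotation.has_label(lbl) for lbl in ("CE2", "LG2", "CE3"))
    evidence = [f"ec_count={ec_count}", f"CE2_LG2_CE3={'present' if has_block else 'absent'}"]
    if has_block:
        if 14 <= ec_count <= 17:
            typ = "III"
            evidence.append("rule: full membrane-proximal block + 14..17 ECs -> III")
        else:
            typ = "non_categorized"
            evidence.append(
                "rule: full membrane-proximal block but EC count outside 14..17"
            )
    else:
        if ec_count == 7:
            typ = "IVa"
            evidence.append("rule: no CE2/LG2/CE3 + 7 ECs -> IVa")
        elif ec_count == 9:
            typ = "IVb"
            evidence.append("rule: no CE2/LG2/CE3 + 9 ECs -> IVb")
        else:
            typ = "non_categorized"
            if ec_count == 8:
                log.warning(
                    "%s: 8-EC type IV architecture is undefined; "
                    "returning non_categorized", annotation.record_id,
                )
                evidence.append("rule: 8-EC type IV variant is undefined")
            else:
                evidence.append("rule: no matching type rule")
    return CadherinTypeCall(
        record_id=annotation.record_id,
        type=typ,
        ec_count=ec_count,
        has_CE2_LG2_CE3=has_block,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# One-call annotation

def annotate(protein: ProteinRecord,
             reference: DomainAnnotation | None = None,
             reference_protein: ProteinRecord | None = None,
             params: AlignmentParams | None = None,
             min_ec_len: int = 85, max_ec_len: int = 140) -> DomainAnnotation:
    """Full de novo (or reference-transferred) domain annotation.

    With a reference annotation + its protein, domains are transferred
    through a global alignment (the reference-first scheme); otherwise the
    linker-motif / hydropathy / cysteine-cluster detectors are used.
    """
    if reference is not None:
        if reference_protein is None:
            raise ValueError("reference transfer needs the reference protein")
        aln = global_align(reference_protein.sequence, protein.sequence,
                           params or AlignmentParams())
        ann = transfer_domains(reference, aln)
        ann.record_id = protein.id
        return ann

    hits = scan_linker_motifs(protein)
    ecs = segment_ec_domains(protein, hits, min_ec_len=min_ec_len,
                             max_ec_len=max_ec_len)
    tm, cp = detect_membrane_anchor(protein)
    segments: list[DomainSegment] = []
    if ecs and ecs[0].start > 1:
        segments.append(DomainSegment(label="Nt", klass="Nt", start=1,
                                      end=ecs[0].start - 1))
    segments.extend(ecs)
    ec_end = ecs[-1].end if ecs else 0
    tm_start = tm.start if tm else len(protein.sequence) + 1
    if ec_end and tm_start - ec_end > 1:
        segments.extend(
            detect_membrane_proximal(protein.sequence, ec_end, tm_start)
        )
    if tm is not None:
        segments.append(tm)
    if cp is not None:
        segments.append(cp)
    if tm is None:
        log.warning("%s: no transmembrane window above threshold", protein.id)
    return DomainAnnotation(record_id=protein.id, segments=segments)
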