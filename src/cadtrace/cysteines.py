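"""Cysteine-pattern profiling and lineage-restricted conservation calls.

Cysteines in each protein are grouped into local pattern runs — solitary
(-C-), paired (-C-C-), or spaced by one residue (-C-X-C-) — then projected
through a reference alignment into per-column, per-taxon-group occupancy
fractions, from which stable / lineage-gain / lineage-loss / sporadic
conservation calls are made.  A short C-terminal E-[S/A]-W-C motif is
detected separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .records import MultipleAlignment, ProteinRecord, ValidationError

PATTERN_CLASSES = ("solitary", "CC", "CXC")
CONSERVATION_STATUSES = ("stable", "lineage_gain", "lineage_loss", "sporadic")


@dataclass
class CysteineMap:
    """Positions and local pattern runs of the cysteines of one protein."""

    record_id: str
    positions: list[int]  # sorted 1-based residue indices
    pattern_runs: list[tuple[int, str]]  # (start position, pattern class)


def cysteine_map(protein: ProteinRecord | str,
                 record_id: str = "") -> CysteineMap:
    """Greedy left-to-right pattern assignment: CC pairs first, then CXC
    among the remaining cysteines, then solitary.

    Every cysteine belongs to exactly one run; e.g. "CCC" yields a CC run at
    the first position and a solitary at the third.
    """
    if isinstance(protein, ProteinRecord):
        seq, record_id = protein.sequence, protein.id
    else:
        seq = protein
    positions = [i + 1 for i, ch in enumerate(seq) if ch == "C"]
    unassigned = set(positions)
    runs: list[tuple[int, str]] = []
    for p in positions:  # CC pass
        if p in unassigned and p + 1 in unassigned:
            runs.append((p, "CC"))
            unassigned.discard(p)
            unassigned.discard(p + 1)
    for p in positions:  # CXC pass
        if p in unassigned and p + 2 in unassigned and seq[p] != "C":
            runs.append((p, "CXC"))
            unassigned.discard(p)
            unassigned.discard(p + 2)
    for p in positions:
        if p in unassigned:
            runs.append((p, "solitary"))
            unassigned.discard(p)
    runs.sort()
    return CysteineMap(record_id=record_id, positions=positions,
                       pattern_runs=runs)


def project_cysteines(alignment: MultipleAlignment,
                      groups: dict[str, str]) -> pd.DataFrame:
    """Per-column, per-group fraction of sequences carrying a cysteine.

    Rows are alignment columns (1-based, zero-cysteine columns omitted),
    columns are group labels.  Every aligned record must have a group.
    """
    for rid in alignment.ids:
        if rid not in groups:
            raise ValidationError(f"record {rid!r} missing from group table")
    labels = sorted(set(groups[rid] for rid in alignment.ids))
    group_members = {
        lab: [rid for rid in alignment.ids if groups[rid] == lab]
        for lab in labels
    }
    counts: dict[int, dict[str, int]] = {}
    for rid, gapped in alignment.rows:
        lab = groups[rid]
        for col0, ch in enumerate(gapped):
            if ch == "C":
                counts.setdefault(col0 + 1, {}).setdefault(lab, 0)
                counts[col0 + 1][lab] += 1
    rows = []
    for col in sorted(counts):
        rows.append(
            {
                "column": col,
                **{
                    lab: counts[col].get(lab, 0) / len(group_members[lab])
                    for lab in labels
                },
            }
        )
    df = pd.DataFrame(rows, columns=["column", *labels])
    return df.set_index("column") if rows else pd.DataFrame(columns=labels)


@dataclass
class ConservationCall:
    alignment_column: int
    occupancy: dict[str, float]
    status: str
    groups_implicated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in CONSERVATION_STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        for v in self.occupancy.values():
            if not 0.0 <= v <= 1.0:
                raise ValidationError("occupancy fractions must be in [0,1]")


def call_conservation(occupancy: pd.DataFrame,
                      stable_threshold: float = 0.8
                      ) -> list[ConservationCall]:
    """Classify every cysteine-bearing column across taxon groups.

    stable: occupancy ≥ threshold in every group; lineage_loss: ≥ threshold
    in all groups but one, and exactly 0 in that one; lineage_gain: the
    symmetric case; sporadic otherwise.  Needs at least two groups.
    """
    labels = list(occupancy.columns)
    if len(labels) < 2:
        raise ValidationError("conservation calls need at least two groups")
    calls: list[ConservationCall] = []
    for col, row in occupancy.iterrows():
        occ = {lab: float(row[lab]) for lab in labels}
        high = [lab for lab in labels if occ[lab] >= stable_threshold]
        zero = [lab for lab in labels if occ[lab] == 0.0]
        if len(high) == len(labels):
            status, implicated = "stable", []
        elif len(high) == len(labels) - 1 and len(zero) == 1 and \
                zero[0] not in high:
            status, implicated = "lineage_loss", zero
        elif len(high) == 1 and len(zero) == len(labels) - 1 and \
                high[0] not in zero:
            status, implicated = "lineage_gain", high
        else:
            status, implicated = "sporadic", []
        calls.append(
            ConservationCall(alignment_column=int(col), occupancy=occ,
                             status=status, groups_implicated=implicated)
        )
    return calls


_CTERM_MOTIF = re.compile(r"E[SA]WC")


def cterm_motif(protein: ProteinRecord | str) -> tuple[bool, tuple[int, int] | None]:
    """Detect the C-terminal E-[S/A]-W-C motif.

    True iff the motif occurs with its cysteine among the last three
    residues of the protein.  Returns the matched span (1-based inclusive)
    when found.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if len(seq) < 4:
        raise ValidationError("sequence shorter than the motif")
    L = len(seq)
    for m in _CTERM_MOTIF.finditer(seq):
        c_pos = m.end()  # 1-based position of the C
        if c_pos >= L - 2:
            return True, (m.start() + 1, m.end())
    return False, None
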