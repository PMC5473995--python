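"""Exon-intron structure inference and intron-position conservation mapping.

A transcript is mapped back onto its genomic region by exact-match seeding
under the GT-AG splicing rule, giving a gene model; each intron is then
projected into protein coordinates as a (residue position, phase) site,
homologized across genes through a multiple alignment as (alignment column,
phase) keys, and classified into cross-taxon conservation categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import (
    GeneModel,
    MultipleAlignment,
    NucleotideRecord,
    ValidationError,
)

log = logging.getLogger(__name__)


class SpliceInferenceError(ValueError):
    """The transcript could not be reconstructed from the genomic sequence.

    Carries the unplaced transcript interval (0-based half-open).
    """

    def __init__(self, message: str, unplaced: tuple[int, int]):
        super().__init__(message)
        self.unplaced = unplaced


def _find_orf(transcript: str) -> tuple[int, int]:
    """Longest ATG..stop open reading frame; returns (offset, cds_length)."""
    stops = {"TAA", "TAG", "TGA"}
    best = (0, 0)  # (length, offset)
    n = len(transcript)
    for frame in range(3):
        i = frame
        start = None
        while i + 3 <= n:
            codon = transcript[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                length = i + 3 - start
                if length > best[0]:
                    best = (length, start)
                start = None
            i += 3
    if best[0] == 0:
        raise ValidationError("no complete open reading frame in transcript")
    return best[1], best[0]


def infer_gene_structure(transcript: NucleotideRecord,
                         genomic: NucleotideRecord,
                         seed_len: int = 20, max_shift: int = 10,
                         min_intron: int = 30,
                         find_cds: bool = True) -> GeneModel:
    """Infer exon coordinates by comparing transcript and genomic sequences.

    Exons are anchored by maximal exact matches; at each splice point the
    next exon is located with a ``seed_len``-mer seed, and the boundary is
    adjusted within ``max_shift`` nt so that the intron starts with GT and
    ends with AG.  Residual ambiguity is resolved to the leftmost donor.
    Concatenating the exons reproduces the transcript exactly.
    """
    t = transcript.sequence
    g = genomic.sequence
    exons: list[tuple[int, int]] = []  # 0-based half-open genomic
    ti = 0  # transcript cursor
    gi = 0  # genomic search origin for the current exon
    # locate the first exon start in the genome
    first_seed = t[:seed_len]
    start = g.find(first_seed)
    if start < 0:
        raise SpliceInferenceError(
            "transcript 5' end not found in genomic sequence", (0, len(t))
        )
    gi = start
    while ti < len(t):
        # extend the exact match as far as it goes
        L = 0
        while ti + L < len(t) and gi + L < len(g) and t[ti + L] == g[gi + L]:
            L += 1
        if ti + L == len(t):
            exons.append((gi, gi + L))
            ti += L
            break
        m = ti + L  # first mismatching transcript position
        seed = t[m : m + seed_len]
        if len(seed) < 8:
            raise SpliceInferenceError(
                f"transcript tail too short to anchor after position {m}",
                (m, len(t)),
            )
        candidate = None  # (donor_genomic, exon_end_t, next_exon_genomic)
        search_from = gi + (m - ti) + 1
        p = g.find(seed, search_from)
        while p >= 0 and candidate is None:
            cands_here = []
            for s in range(0, min(max_shift, L, p - 2) + 1):
                e = m - s  # exon ends before transcript position e
                donor = gi + (e - ti)
                acceptor_end = p - s  # next exon starts here (0-based)
                if acceptor_end - donor < min_intron:
                    continue
                if g[donor : donor + 2] != "GT":
                    continue
                if g[acceptor_end - 2 : acceptor_end] != "AG":
                    continue
                if t[e:m] != g[acceptor_end : acceptor_end + s]:
                    continue
                cands_here.append((donor, e, acceptor_end))
            if cands_here:
                candidate = min(cands_here)  # leftmost donor
            else:
                p = g.find(seed, p + 1)
        if candidate is None:
            raise SpliceInferenceError(
                f"no GT-AG-consistent continuation for transcript "
                f"position {m}", (m, len(t)),
            )
        donor, e, nxt = candidate
        exons.append((gi, donor))
        ti = e
        gi = nxt
    rebuilt = "".join(g[s:e] for s, e in exons)
    if rebuilt != t:
        raise SpliceInferenceError(
            "reconstructed exons do not reproduce the transcript",
            (0, len(t)),
        )
    kwargs: dict = {}
    if find_cds:
        offset, cds_len = _find_orf(t)
        kwargs = {"cds_start_offset": offset, "cds_length": cds_len}
    return GeneModel(
        gene_id=transcript.id,
        seq_id=genomic.id,
        strand="+",
        exons=[(s + 1, e) for s, e in exons],
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Intron sites in protein coordinates

@dataclass(frozen=True)
class IntronSite:
    """One intron position expressed on the encoded protein.

    ``protein_position`` is the 1-based residue index of the codon the intron
    interrupts (phase 1/2) or immediately precedes (phase 0); ``phase`` is
    the number of bases of that codon lying 5' of the intron.
    """

    gene_id: str
    protein_position: int
    phase: int
    genomic_donor: int  # 1-based genomic coordinate of the G of GT
    genomic_acceptor: int  # 1-based genomic coordinate of the G of AG
    in_utr: bool = False
    noncanonical: bool = False

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValidationError(f"intron phase must be 0/1/2, got {self.phase}")


def intron_protein_sites(gene: GeneModel,
                         genomic: NucleotideRecord | None = None,
                         allow_noncanonical: bool = False) -> list[IntronSite]:
    """Project each intron of a gene model into protein coordinates.

    Introns in untranslated regions are retained with ``in_utr=True`` but
    excluded from coding-site analyses by callers.  When the genomic
    sequence is supplied, GT-AG boundaries are verified; non-canonical sites
    raise unless ``allow_noncanonical``.
    """
    sites: list[IntronSite] = []
    cds_len = gene.cds_length if gene.cds_length is not None else (
        gene.spliced_length - gene.cds_start_offset
    )
    cum = 0
    for i in range(len(gene.exons) - 1):
        s, e = gene.exons[i]
        cum += e - s + 1
        donor = gene.exons[i][1] + 1
        acceptor = gene.exons[i + 1][0] - 1
        noncanon = False
        if genomic is not None:
            gseq = genomic.sequence
            dn = gseq[donor - 1 : donor + 1]
            ac = gseq[acceptor - 2 : acceptor]
            if dn != "GT" or ac != "AG":
                noncanon = True
                if not allow_noncanonical:
                    raise ValidationError(
                        f"{gene.gene_id}: non-canonical splice site "
                        f"{dn}..{ac} at intron {i + 1}"
                    )
        coding_offset = cum - gene.cds_start_offset
        if coding_offset <= 0 or coding_offset >= cds_len:
            sites.append(
                IntronSite(gene_id=gene.gene_id, protein_position=0, phase=0,
                           genomic_donor=donor, genomic_acceptor=acceptor,
                           in_utr=True, noncanonical=noncanon)
            )
            continue
        phase = coding_offset % 3
        position = coding_offset // 3 + 1 if phase else coding_offset // 3 + 1
        # phase 0: intron sits between codons; convention assigns it to the
        # following codon, i.e. position = coding_offset/3 + 1
        if phase == 0:
            position = coding_offset // 3 + 1
        sites.append(
            IntronSite(gene_id=gene.gene_id, protein_position=position,
                       phase=phase, genomic_donor=donor,
                       genomic_acceptor=acceptor, noncanonical=noncanon)
        )
    return sites


def coding_sites(sites: list[IntronSite]) -> list[IntronSite]:
    return [s for s in sites if not s.in_utr]


# ---------------------------------------------------------------------------
# Homologization across genes

CATEGORIES = (
    "arthropod_specific",
    "spider_plus_nonarthropod",
    "broadly_shared",
    "typeIII_typeIV_shared",
    "nonarthropod_shared",
    "unshared",
)

#: group labels understood by the default classifier predicates
GROUP_ROLES = ("spider", "arthropod_typeIII", "arthropod_typeIV", "non_arthropod")


@dataclass
class IntronSiteMatrix:
    """Homologized intron sites: (alignment column, phase) keys × genes."""

    presence: pd.DataFrame  # bool, index=gene ids, columns=(column, phase)
    categories: dict[tuple[int, int], str] = field(default_factory=dict)
    notes: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def site_keys(self) -> list[tuple[int, int]]:
        return list(self.presence.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)


def project_sites(sites_by_gene: dict[str, list[IntronSite]],
                  alignment: MultipleAlignment) -> IntronSiteMatrix:
    """Homologize per-gene intron sites through an alignment.

    Two sites are homologous iff they land in the same alignment column with
    the same phase.  Sites whose residue lies outside the aligned row raise;
    UTR sites are skipped.
    """
    keys: dict[tuple[int, int], dict[str, bool]] = {}
    for gene_id, sites in sites_by_gene.items():
        cmap = alignment.column_map(gene_id)
        for site in coding_sites(sites):
            if site.protein_position > cmap.n_residues:
                log.warning(
                    "%s: intron site at residue %d beyond aligned sequence "
                    "(%d residues); unmappable", gene_id,
                    site.protein_position, cmap.n_residues,
                )
                continue
            key = (cmap.column_of(site.protein_position), site.phase)
            keys.setdefault(key, {})[gene_id] = True
    genes = list(sites_by_gene)
    columns = sorted(keys)
    data = {
        key: [keys[key].get(g, False) for g in genes] for key in columns
    }
    presence = pd.DataFrame(data, index=genes)
    presence.columns = pd.Index(columns)
    return IntronSiteMatrix(presence=presence)


def classify_sites(matrix: IntronSiteMatrix,
                   groups: dict[str, str]) -> IntronSiteMatrix:
    """Assign each homologized site a cross-taxon conservation category.

    ``groups`` maps every gene to one of ``GROUP_ROLES``.  Categories, in
    order of precedence:

    - broadly_shared: spider + another arthropod + a non-arthropod;
    - spider_plus_nonarthropod: spider + non-arthropod, no other arthropod;
    - typeIII_typeIV_shared: a non-spider arthropod type III gene and an
      arthropod type IV gene, absent from spiders and non-arthropods;
    - arthropod_specific: spider + another arthropod, no non-arthropod;
    - nonarthropod_shared: ≥2 non-arthropods and no arthropod;
    - unshared otherwise (a note marks within-lineage-only sharing).
    """
    for g in matrix.genes:
        if g not in groups:
            raise ValidationError(f"gene {g!r} has no taxon-group assignment")
        if groups[g] not in GROUP_ROLES:
            raise ValidationError(
                f"gene {g!r}: unknown group {groups[g]!r} "
                f"(expected one of {GROUP_ROLES})"
            )
    categories: dict[tuple[int, int], str] = {}
    notes: dict[tuple[int, int], str] = {}
    for key in matrix.site_keys:
        present = [g for g in matrix.genes if matrix.presence.loc[g, key]]
        roles = [groups[g] for g in present]
        n_spider = roles.count("spider")
        n_arth3 = roles.count("arthropod_typeIII")
        n_arth4 = roles.count("arthropod_typeIV")
        n_nonarth = roles.count("non_arthropod")
        n_other_arth = n_arth3 + n_arth4
        if n_spider and n_other_arth and n_nonarth:
            cat = "broadly_shared"
        elif n_spider and n_nonarth and not n_other_arth:
            cat = "spider_plus_nonarthropod"
        elif n_arth3 and n_arth4 and not n_spider and not n_nonarth:
            cat = "typeIII_typeIV_shared"
        elif n_spider and n_other_arth and not n_nonarth:
            cat = "arthropod_specific"
        elif n_nonarth >= 2 and not n_spider and not n_other_arth:
            cat = "nonarthropod_shared"
        else:
            cat = "unshared"
            if len(present) >= 2:
                notes[key] = "shared only within one lineage"
        categories[key] = cat
    return IntronSiteMatrix(presence=matrix.presence, categories=categories,
                            notes=notes)


def summarize_conservation(matrix: IntronSiteMatrix, k: int = 4,
                           subset: list[str] | None = None) -> dict:
    """Deterministic summary counts of a categorized site matrix.

    ``shared_by_k``: number of site keys present in at least ``k`` genes of
    ``subset`` (default: all genes).
    """
    genes = matrix.genes if subset is None else list(subset)
    missing = set(genes) - set(matrix.genes)
    if missing:
        raise ValidationError(f"subset genes not in matrix: {sorted(missing)}")
    sub = matrix.presence.loc[genes]
    shared_by_k = int((sub.sum(axis=0) >= k).sum())
    per_gene = matrix.presence.sum(axis=1).astype(int).to_dict()
    per_category: dict[str, int] = {c: 0 for c in CATEGORIES}
    for key, cat in matrix.categories.items():
        per_category[cat] += 1
    return {
        "n_sites": len(matrix.site_keys),
        "k": k,
        "subset_size": len(genes),
        "shared_by_k": shared_by_k,
        "per_gene": per_gene,
        "per_category": per_category,
    }


def sites_table(matrix: IntronSiteMatrix,
                sites_by_gene: dict[str, list[IntronSite]],
                alignment: MultipleAlignment) -> pd.DataFrame:
    """Long-format TSV-ready table: gene, position, phase, column, category."""
    rows = []
    for gene_id, sites in sites_by_gene.items():
        cmap = alignment.column_map(gene_id)
        for site in coding_sites(sites):
            if site.protein_position > cmap.n_residues:
                continue
            key = (cmap.column_of(site.protein_position), site.phase)
            rows.append(
                {
                    "gene_id": gene_id,
                    "protein_position": site.protein_position,
                    "phase": site.phase,
                    "column": key[0],
                    "category": matrix.categories.get(key, ""),
                }
            )
    return pd.DataFrame(rows)
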