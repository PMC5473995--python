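"""End-to-end orchestration: annotate → dotplot → introns → cysteines.

The pipeline consumes a directory-style set of inputs (protein FASTA,
optional transcript+genomic FASTA pairs, optional precomputed alignment,
taxon-group TSV), runs the configured stages, writes per-stage TSVs and a
JSON summary whose every number is taken from the stage tables, and logs
all parameters.  Deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as _align
from . import cysteines as _cys
from . import domains as _dom
from . import introns as _intr
from . import io as _io
from .records import ValidationError

log = logging.getLogger("cadtrace.pipeline")


@dataclass
class PipelineConfig:
    """All stage parameters with the study's printed constants as defaults
    (window 120, step 5, shared-by-k 4; the legacy genome-screen E-value
    cutoff 1e-4 is carried as provenance metadata only)."""

    proteins: str = ""
    groups: str = ""
    alignment: str = ""
    transcripts: str = ""
    genomes: str = ""
    out_dir: str = "cadtrace_out"
    seed: int = 0
    # stage toggles
    run_annotate: bool = True
    run_dotplot: bool = True
    run_introns: bool = True
    run_cysteines: bool = True
    # dotplot parameters
    reference_id: str = ""  # default: first protein
    window_width: int = 120
    window_step: int = 5
    e_cutoff: float = 1e-3
    gap_tolerance: int = 30
    max_hits_per_window: int = 3
    # intron parameters
    shared_k: int = 4
    shared_subset: list[str] = field(default_factory=list)
    allow_noncanonical: bool = False
    # cysteine parameters
    stable_threshold: float = 0.8
    # provenance only
    discovery_e_cutoff: float = _align.DISCOVERY_EVALUE_CUTOFF

    def validate(self) -> None:
        if self.window_width < 1 or self.window_step < 1:
            raise ValidationError("window width/step must be >= 1")
        if not 0 < self.e_cutoff:
            raise ValidationError("e_cutoff must be positive")
        if not 0 < self.stable_threshold <= 1:
            raise ValidationError("stable_threshold must be in (0, 1]")
        if self.shared_k < 1:
            raise ValidationError("shared_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline parameters: %s", asdict(config))

    if not config.proteins:
        raise ValidationError("no protein FASTA configured")
    proteins = _io.read_fasta(config.proteins, alphabet="protein")
    if not proteins:
        raise ValidationError(f"{config.proteins}: no records")
    groups = _io.read_groups(config.groups) if config.groups else {}
    summary: dict = {"seed": config.seed, "n_proteins": len(proteins)}

    annotations = {}
    if config.run_annotate:
        try:
            rows = []
            anns = []
            for rec in proteins:
                ann = _dom.annotate(rec)
                call = _dom.classify_cadherin(ann)
                annotations[rec.id] = ann
                anns.append(ann)
                rows.append(
                    {
                        "record_id": rec.id,
                        "type": call.type,
                        "ec_count": call.ec_count,
                        "domain_string": ann.domain_string(),
                    }
                )
            df = pd.DataFrame(rows)
            df.to_csv(out / "annotations.tsv", sep="\t", index=False)
            _io.write_annotations_gff(anns, out / "annotations.gff3")
            summary["type_calls"] = dict(zip(df.record_id, df.type))
            summary["ec_counts"] = dict(zip(df.record_id, df.ec_count.astype(int)))
        except Exception as exc:  # noqa: BLE001 - re-raise structured
            raise StageError("annotate", str(exc)) from exc

    if config.run_dotplot and len(proteins) >= 2:
        try:
            ref_id = config.reference_id or proteins[0].id
            reference = next(p for p in proteins if p.id == ref_id)
            hit_frames = []
            seg_rows = []
            identities = {}
            for rec in proteins:
                if rec.id == ref_id:
                    continue
                dp = _align.dotplot(
                    rec, reference, e_cutoff=config.e_cutoff,
                    width=config.window_width, step=config.window_step,
                    gap_tolerance=config.gap_tolerance,
                    max_hits_per_window=config.max_hits_per_window,
                )
                frame = dp.hits_table()
                frame.insert(0, "query_id", rec.id)
                hit_frames.append(frame)
                for i, seg in enumerate(dp.segments):
                    seg_rows.append(
                        {
                            "query_id": rec.id, "segment": i,
                            "q_start": seg.q_range[0], "q_end": seg.q_range[1],
                            "ref_start": seg.ref_range[0],
                            "ref_end": seg.ref_range[1],
                            "mean_offset": seg.mean_offset,
                            "n_hits": len(seg.hits),
                        }
                    )
                aln = _align.global_align(rec.sequence, reference.sequence)
                identities[rec.id] = round(_align.percent_identity(aln), 1)
            if hit_frames:
                pd.concat(hit_frames).to_csv(out / "dotplot_hits.tsv",
                                             sep="\t", index=False)
            pd.DataFrame(seg_rows).to_csv(out / "dotplot_segments.tsv",
                                          sep="\t", index=False)
            summary["reference_id"] = ref_id
            summary["percent_identity_vs_reference"] = identities
        except Exception as exc:  # noqa: BLE001
            raise StageError("dotplot", str(exc)) from exc

    if config.run_introns and config.transcripts and config.genomes:
        try:
            transcripts = _io.read_fasta(config.transcripts,
                                         alphabet="nucleotide",
                                         kind="transcript")
            genomes = {
                g.id: g
                for g in _io.read_fasta(config.genomes, alphabet="nucleotide")
            }
            models = []
            sites_by_gene = {}
            for t in transcripts:
                genomic = genomes.get(f"{t.id}_genomic") or genomes.get(t.id)
                if genomic is None:
                    raise ValidationError(f"no genomic sequence for {t.id}")
                model = _intr.infer_gene_structure(t, genomic)
                models.append(model)
                sites_by_gene[t.id] = _intr.intron_protein_sites(
                    model, genomic,
                    allow_noncanonical=config.allow_noncanonical,
                )
            _io.write_gene_models(models, out / "gene_models.gff3")
            summary["exon_counts"] = {m.gene_id: len(m.exons) for m in models}
            if config.alignment:
                alignment = _io.read_alignment(config.alignment)
                matrix = _intr.project_sites(sites_by_gene, alignment)
                if groups:
                    matrix = _intr.classify_sites(
                        matrix, {g: meta["group"] for g, meta in groups.items()}
                    )
                table = _intr.sites_table(matrix, sites_by_gene, alignment)
                table.to_csv(out / "intron_sites.tsv", sep="\t", index=False)
                conservation = _intr.summarize_conservation(
                    matrix, k=config.shared_k,
                    subset=config.shared_subset or None,
                )
                summary["intron_conservation"] = conservation
        except Exception as exc:  # noqa: BLE001
            raise StageError("introns", str(exc)) from exc

    if config.run_cysteines and config.alignment and groups:
        try:
            alignment = _io.read_alignment(config.alignment)
            label_of = {g: meta["group"] for g, meta in groups.items()}
            occ = _cys.project_cysteines(alignment, label_of)
            calls = _cys.call_conservation(occ, config.stable_threshold)
            pd.DataFrame(
                [
                    {
                        "column": c.alignment_column,
                        "status": c.status,
                        "groups_implicated": ",".join(c.groups_implicated),
                        **{f"occ_{g}": v for g, v in c.occupancy.items()},
                    }
                    for c in calls
                ]
            ).to_csv(out / "cysteine_calls.tsv", sep="\t", index=False)
            motif_rows = []
            for rec in proteins:
                found, span = _cys.cterm_motif(rec)
                motif_rows.append(
                    {"record_id": rec.id, "cterm_motif": found,
                     "span": f"{span[0]}-{span[1]}" if span else ""}
                )
            pd.DataFrame(motif_rows).to_csv(out / "cterm_motifs.tsv",
                                            sep="\t", index=False)
            summary["cysteine_status_counts"] = (
                pd.Series([c.status for c in calls]).value_counts().to_dict()
            )
            summary["cterm_motif"] = {
                r["record_id"]: bool(r["cterm_motif"]) for r in motif_rows
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("cysteines", str(exc)) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True, default=int))
    return summary
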