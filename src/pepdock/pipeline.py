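"""End-to-end docking pipeline: rank templates, build and refine models,
report predicted binding sites and estimated accuracy."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import config
from .contacts import binding_site, detect_contacts
from .evaluate import (SYNTHETIC_DEFAULT_ACCURACY_MODEL, AccuracyModel,
                       QualityReport, estimate_accuracy, evaluate_model)
from .modeling import DockModel, generate_models
from .similarity import ScoredTemplate, rank_templates, select_templates
from .structure_io import (PeptideSequence, Structure, parse_fasta,
                           parse_structure, write_complex)
from .template_db import TemplateDB, load_database

logger = logging.getLogger(__name__)


class InputLimitError(ValueError):
    """Query exceeds the protein/peptide size limits."""


@dataclass
class RunConfig:
    db_path: str | Path | None = None
    protein_pdb: str | Path | None = None
    peptide_fasta: str | Path | None = None
    output_dir: str | Path | None = None
    n_models: int = config.N_OUTPUT_MODELS
    seed: int = 0
    force: bool = False
    modeling: config.ModelingConfig = field(default_factory=config.ModelingConfig)

    def __post_init__(self):
        if not (1 <= self.n_models <= config.N_OUTPUT_MODELS):
            raise ValueError(f"n_models must be in [1, {config.N_OUTPUT_MODELS}]")


@dataclass
class PipelineResult:
    models: list[DockModel]
    ranked: list[ScoredTemplate]
    selected: list[ScoredTemplate]
    predicted_binding_site: list[tuple[str, int]]
    estimated_accuracy: float
    low_accuracy: bool
    report: dict


def _check_limits(protein: Structure, peptide: PeptideSequence, force: bool):
    if protein.n_residues > config.MAX_PROTEIN_LENGTH and not force:
        raise InputLimitError(
            f"protein has {protein.n_residues} residues "
            f"(limit {config.MAX_PROTEIN_LENGTH}); use force to override")
    if len(peptide) > config.MAX_PEPTIDE_LENGTH and not force:
        raise InputLimitError(
            f"peptide has {len(peptide)} residues "
            f"(limit {config.MAX_PEPTIDE_LENGTH}); use force to override")


def ranking_tsv(ranked: list[ScoredTemplate],
                selected: list[ScoredTemplate]) -> str:
    sel_ids = {s.template_id for s in selected}
    lines = ["template_id\ttm_score\ts_inter\tz_tm\tz_inter\ts_complex\tselected"]
    for s in ranked:
        lines.append(f"{s.template_id}\t{s.tm_score:.6f}\t{s.s_inter:.6f}\t"
                     f"{s.z_tm:.6f}\t{s.z_inter:.6f}\t{s.s_complex:.6f}\t"
                     f"{s.template_id in sel_ids}")
    return "\n".join(lines) + "\n"


def run_pipeline(db: TemplateDB | str | Path,
                 protein: Structure | str,
                 peptide: PeptideSequence | str,
                 cfg: RunConfig | None = None,
                 accuracy_model: AccuracyModel | None = None) -> PipelineResult:
    """Dock a peptide sequence onto a protein using the template database.

    ``protein``/``peptide`` may be parsed objects or raw PDB/FASTA text.
    Writes ``model_XX.pdb``, ``ranking.tsv`` and ``report.json`` into
    ``cfg.output_dir`` when set.
    """
    cfg = cfg or RunConfig()
    if not isinstance(db, TemplateDB):
        db = load_database(db)
    if isinstance(protein, str):
        protein = parse_structure(protein, source_id="query")
    if isinstance(peptide, str):
        peptide = parse_fasta(peptide)
    _check_limits(protein, peptide, cfg.force)

    ranked = rank_templates(db, protein, peptide)
    selected = select_templates(ranked)
    if not selected:
        raise ValueError("no templates selected; for template-poor targets "
                         "an ab initio docking server is the better choice")
    models = generate_models(protein, peptide, selected, db,
                             cfg.modeling, cfg.seed, cfg.n_models)

    best = models[0]
    cm = detect_contacts(best.protein, best.peptide)
    site_idx = sorted(binding_site(cm))
    prot_res = best.protein.residues
    site = [(prot_res[i].chain_id, prot_res[i].author_number) for i in site_idx]

    am = accuracy_model or SYNTHETIC_DEFAULT_ACCURACY_MODEL
    top = selected[0]
    est, low = estimate_accuracy(am, top.tm_score, top.s_inter_normalized)

    report = {
        "n_templates_searched": len(db),
        "templates_selected": [s.template_id for s in selected],
        "ranking": [
            {"template_id": s.template_id, "tm_score": s.tm_score,
             "s_inter": s.s_inter, "z_tm": s.z_tm, "z_inter": s.z_inter,
             "s_complex": s.s_complex}
            for s in ranked
        ],
        "models": [
            {"rank": k + 1, "template_id": m.template_id, "seed": m.seed,
             "energy": {"clash": m.energy_components[0],
                        "restraint": m.energy_components[1],
                        "total": m.energy_components[2]}}
            for k, m in enumerate(models)
        ],
        "predicted_binding_site": [[c, n] for c, n in site],
        "estimated_accuracy": est,
        "low_accuracy_warning": low,
        "seed": cfg.seed,
    }

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, m in enumerate(models, start=1):
            (out / f"model_{k:02d}.pdb").write_text(write_complex(m))
        (out / "ranking.tsv").write_text(ranking_tsv(ranked, selected))
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))

    return PipelineResult(models, ranked, selected, site, est, low, report)


def evaluate_command(model_pdb: str, native_pdb: str,
                     peptide_chain_hint: str | None = None) -> QualityReport:
    """CAPRI-style quality of a model complex against the native complex."""
    from .contacts import binding_site_recovery
    from .template_db import split_complex

    model_s = parse_structure(model_pdb, source_id="model")
    native_s = parse_structure(native_pdb, source_id="native")
    try:
        mp, mpep = split_complex(model_s, peptide_chain_hint)
        np_, npep = split_complex(native_s, peptide_chain_hint)
    except ValueError as exc:
        raise ValueError(
            f"{exc}; pass a peptide chain hint matching both files") from exc
    shared = {r.key for r in mp.residues} & {r.key for r in np_.residues}
    if not shared:
        raise ValueError(
            "model and native share no protein residues; chain ids/"
            "numbering must match (consider renaming chains)")
    bsf = None
    try:
        native_site = binding_site(detect_contacts(np_, npep))
        model_site = binding_site(detect_contacts(mp, mpep))
        nat_keys = {np_.residues[i].key for i in native_site}
        mod_keys = {mp.residues[i].key for i in model_site}
        bsf = len(mod_keys & nat_keys) / len(nat_keys) if nat_keys else None
    except ValueError:
        pass
    return evaluate_model(mp, mpep, np_, npep, binding_site_fraction=bsf)
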