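"""End-to-end analysis: structure -> mechanical model -> rigidity scan ->
conservation scores -> combined per-residue verdicts -> reports.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import conservation as cons_mod
from . import criticality as crit_mod
from .config import Config
from .mechanical_model import BarPolicy, build_model
from .mutagen import mutation_scan, outcomes_to_tsv
from .pebble_game import pebble_analyze
from .structure_model import (
    HBondParams,
    compute_sasa,
    detect_covalent_bonds,
    detect_hydrogen_bonds,
    detect_hydrophobic_tethers,
    interactions_to_tsv,
    read_structure,
)

__all__ = ["ReportBundle", "PipelineError", "run_pipeline", "sniff_dialect"]

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class ReportBundle:
    config: Config
    structure: object
    interactions: list
    rigidity: object                 # wild-type RigidityResult
    outcomes: list                   # MutationOutcome per residue
    profile: object                  # ConservationProfile
    verdicts: list
    summary: object                  # ProteinSummary
    confusion: Optional[dict] = None
    sasa: dict = field(default_factory=dict)

    def write(self, outdir) -> dict:
        """Write the bundle as TSV/JSON files; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["interactions"] = outdir / "interactions.tsv"
        paths["interactions"].write_text(interactions_to_tsv(self.interactions))
        paths["mutscan"] = outdir / "mutscan.tsv"
        paths["mutscan"].write_text(outcomes_to_tsv(self.outcomes))
        paths["conservation"] = outdir / "conservation.tsv"
        paths["conservation"].write_text(
            cons_mod.profile_to_tsv(self.profile, self.config.tau_c))
        paths["verdicts"] = outdir / "verdicts.tsv"
        paths["verdicts"].write_text(crit_mod.verdicts_to_tsv(self.verdicts))

        report = {
            "config": self.config.as_dict(),
            "structure": self.structure.name,
            "n_residues": len(self.structure.residues),
            "n_atoms": self.structure.n_atoms,
            "n_interactions": len(self.interactions),
            "wild_type_lrb_atoms": self.rigidity.lrb_atoms,
            "wild_type_free_dof": self.rigidity.free_dof,
            "summary": vars(self.summary),
        }
        if self.confusion is not None:
            report["confusion"] = self.confusion
        paths["report"] = outdir / "report.json"
        paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True)
                                   + "\n")
        return paths


def sniff_dialect(text: str) -> str:
    """Guess the rank-file dialect: '%' headers mean an ET-server file."""
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("%"):
            return "et_server"
        return "tsv" if "\t" in line else "et_server"
    return "tsv"


def detect_all_interactions(structure, config: Config) -> list:
    covalent = detect_covalent_bonds(structure, config.covalent_tolerance)
    hbonds = detect_hydrogen_bonds(
        structure,
        HBondParams(config.hbond_max_distance, config.hbond_min_angle,
                    config.hbond_bars),
        covalent=covalent)
    tethers = detect_hydrophobic_tethers(
        structure, config.hydrophobic_slack, config.hydrophobic_bars)
    return covalent + hbonds + tethers


def run_pipeline(pdb_path, ranks_path, ddg_path=None,
                 config: Optional[Config] = None,
                 compute_sasa_map: bool = False) -> ReportBundle:
    """Run the full combined conservation + rigidity analysis.

    Raises :class:`PipelineError` when the residue numbering of the rank file
    does not match the structure.
    """
    config = (config or Config()).validate()
    for key, val in sorted(config.as_dict().items()):
        logger.info("config %s = %r", key, val)

    pdb_text = Path(pdb_path).read_text()
    structure = read_structure(pdb_text, model_index=config.model_index,
                               name=Path(pdb_path).stem)
    interactions = detect_all_interactions(structure, config)

    model = build_model(structure, interactions,
                        BarPolicy(config.hbond_bars, config.hydrophobic_bars))
    rigidity = pebble_analyze(model.graph, model=model)

    outcomes = mutation_scan(
        structure, interactions, config.mutation_target, tau_r=config.tau_r,
        bar_policy=BarPolicy(config.hbond_bars, config.hydrophobic_bars))

    ranks_text = Path(ranks_path).read_text()
    dialect = (sniff_dialect(ranks_text) if config.ranks_dialect == "auto"
               else config.ranks_dialect)
    ranks = cons_mod.parse_et_ranks(ranks_text, dialect)
    chain_id = structure.residues[0].residue_key[0]
    profile = cons_mod.conservation_scores(ranks, config.sigma_mode, chain_id)
    cons_flags = cons_mod.conservation_critical(profile, config.tau_c)

    struct_positions = {r.residue_key[1] for r in structure.residues}
    unmatched = sorted(set(ranks) ^ struct_positions)
    if unmatched:
        raise PipelineError(
            "residue numbering mismatch between rank file and structure; "
            f"unmatched residues: {unmatched}")

    key_of = {r.residue_key[1]: r.residue_key for r in structure.residues}
    cons_by_key = {key_of[p]: flag for p, flag in cons_flags.items()}
    scores_by_key = {key_of[p]: c for p, c in profile.scores.items()}
    rig_by_key = {o.residue_key: o.rigidity_critical for o in outcomes}
    pct_by_key = {o.residue_key: o.pct_decrease for o in outcomes}

    verdicts = crit_mod.combine_verdicts(cons_by_key, rig_by_key,
                                         scores_by_key, pct_by_key)
    summary = crit_mod.protein_summary(verdicts, structure.name)

    confusion = None
    if ddg_path is not None:
        records = crit_mod.parse_ddg_tsv(Path(ddg_path).read_text())
        confusion = crit_mod.confusion_vs_experiment(
            verdicts, records, (config.ddg_window_lo, config.ddg_window_hi))

    sasa = compute_sasa(structure, config.sasa_probe,
                        config.sasa_points) if compute_sasa_map else {}

    return ReportBundle(config=config, structure=structure,
                        interactions=interactions, rigidity=rigidity,
                        outcomes=outcomes, profile=profile, verdicts=verdicts,
                        summary=summary, confusion=confusion, sasa=sasa)
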