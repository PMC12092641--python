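"""End-to-end pipeline: events -> bouts -> networks -> centrality ->
cognition -> lesions -> mixed models, with persisted intermediates and a
run manifest.

The pipeline consumes either real input CSVs (events, roster, trials,
lesions) or a synthetic-generation block, never both.  Every stage writes
its intermediate output to the run directory as CSV/GraphML so any stage
can be inspected or re-run, and the manifest records the seed, the
resolved configuration and a content hash per output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .bouts import segment_fights
from .centrality import centrality_table, redundancy_screen
from .cognition import load_trials, profiles_from_frame, profiles_to_frame
from .ethogram import default_ethogram
from .events import (
    OBSERVATION_WINDOW_S,
    filter_subtle,
    frame_to_events,
    involvement_seconds,
)
from .lesions import lesion_outcomes, load_lesions
from .models import ModelSpec, fit_full_and_compare, fit_null, fit_report
from .networks import (
    NET_TYPES,
    build_network,
    simplify,
    validate_roster,
    write_edge_csv,
    write_graphml,
)
from .synthetic import EffectConfig, generate_study

logger = logging.getLogger("pignet")

DEFAULT_MODEL_GRID = (
    {"outcome": "uni_w_degree", "cognitive_term": "reversal_passed"},
    {"outcome": "uni_w_degree", "cognitive_term": "learning_category"},
    {"outcome": "all_w_degree", "cognitive_term": "reversal_passed"},
)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    synthetic: Optional[dict] = None  # {"n_pens": int, "effects": {...}}
    inputs: Optional[dict] = None  # {"events":..., "roster":..., ...}
    networks: tuple[str, ...] = NET_TYPES
    model_grid: tuple[dict, ...] = DEFAULT_MODEL_GRID
    observation_window_s: float = OBSERVATION_WINDOW_S

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'synthetic' or 'inputs'"
            )
        unknown = set(self.networks) - set(NET_TYPES)
        if unknown:
            raise ValueError(f"unknown network types: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if outdir is not None:
            doc["outdir"] = outdir
        if seed is not None:
            doc["seed"] = seed
        doc.setdefault("outdir", "pignet_run")
        if "networks" in doc:
            doc["networks"] = tuple(doc["networks"])
        if "model_grid" in doc:
            doc["model_grid"] = tuple(doc["model_grid"])
        return cls(**doc)

    def to_mapping(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "synthetic": self.synthetic,
            "inputs": self.inputs,
            "networks": list(self.networks),
            "model_grid": [dict(m) for m in self.model_grid],
            "observation_window_s": self.observation_window_s,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        block = dict(config.synthetic)
        effects = EffectConfig(**block.get("effects", {}))
        study = generate_study(
            n_pens=int(block.get("n_pens", 14)),
            effects=effects,
            seed=config.seed,
            duration_s=config.observation_window_s,
        )
        return study.roster, study.events, study.trials, study.lesions
    paths = config.inputs
    roster = validate_roster(pd.read_csv(paths["roster"], dtype=str).astype(
        {"weight_kg": float}
    ))
    events = pd.read_csv(paths["events"], dtype={"actor": str, "receiver": str})
    if "pen_id" not in events.columns:
        pig_to_pen = dict(zip(roster["pig_id"], roster["pen_id"]))
        events.insert(0, "pen_id", events["actor"].map(pig_to_pen))
    trials = load_trials(paths["trials"]) if paths.get("trials") else pd.DataFrame()
    lesions = load_lesions(paths["lesions"]) if paths.get("lesions") else pd.DataFrame()
    return roster, events, trials, lesions


def analyse_networks(
    roster: pd.DataFrame,
    events_df: pd.DataFrame,
    net_types=NET_TYPES,
    outdir: Optional[Path] = None,
    observation_window_s: float = OBSERVATION_WINDOW_S,
) -> pd.DataFrame:
    """Per-pen network construction and centrality extraction.

    Returns the tidy centrality table across pens and network types; when
    ``outdir`` is given, writes per-pen GraphML and edge lists.
    """
    ethogram = default_ethogram()
    tables = []
    for pen_id, pen_roster in roster.groupby("pen_id"):
        pen_events_df = events_df[events_df["pen_id"] == pen_id].drop(
            columns=["pen_id"]
        )
        events = frame_to_events(
            pen_events_df, ethogram, observation_window_s=observation_window_s
        )
        events = filter_subtle(events, ethogram=ethogram)
        bouts = segment_fights(events, ethogram)
        for net_type in net_types:
            net = simplify(
                build_network(events, bouts, net_type, pen_roster, ethogram)
            )
            if outdir is not None:
                write_graphml(net, outdir / f"{pen_id}_{net_type}.graphml")
                write_edge_csv(net, outdir / f"{pen_id}_{net_type}_edges.csv")
            table = centrality_table(net)
            table.insert(0, "pen_id", pen_id)
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


def assemble_analysis_table(
    roster: pd.DataFrame,
    centrality: pd.DataFrame,
    trials: pd.DataFrame,
    lesions: pd.DataFrame,
) -> pd.DataFrame:
    """One row per pig: metadata, normalised centralities (wide), cognitive
    profile and lesion outcomes, ready for the mixed models."""
    from .networks import nonlittermate_counts

    table = roster.copy()
    table["pig_id"] = table["pig_id"].astype(str)
    nonlit = nonlittermate_counts(roster)
    table["network_size"] = table["pig_id"].map(nonlit)

    wide = centrality.pivot_table(
        index="pig", columns=["net_type", "metric"], values="normalised",
        aggfunc="first",
    )
    wide.columns = [f"{nt.lower()}_{m}" for nt, m in wide.columns]
    table = table.merge(wide, left_on="pig_id", right_index=True, how="left")

    if len(trials):
        profiles = profiles_to_frame(profiles_from_frame(trials))
        profiles["sdt_inclusion"] = True
        profiles = profiles.rename(columns={"pig": "pig_id"})
        table = table.merge(profiles, on="pig_id", how="left")
        table["sdt_inclusion"] = table["sdt_inclusion"].notna() & table[
            "sdt_inclusion"
        ].eq(True)
        table["reversal_inclusion"] = table["reversal_completed"].eq(True)
    if len(lesions):
        outcomes = lesion_outcomes(lesions).rename(columns={"pig": "pig_id"})
        table = table.merge(outcomes, on="pig_id", how="left")
    return table


def run_models(
    table: pd.DataFrame, model_grid, outdir: Optional[Path] = None
) -> pd.DataFrame:
    """Fit the null/full comparison for every grid entry; returns a tidy
    report table and (optionally) writes per-model text reports."""
    rows = []
    reports = []
    for entry in model_grid:
        entry = dict(entry)
        term = entry.pop("cognitive_term", None)
        inclusion = entry.pop("inclusion_term", None)
        spec = ModelSpec(**entry)
        try:
            null_fit = fit_null(table, spec)
            if term is None:
                reports.append(fit_report(null_fit))
                continue
            full_fit, cmp = fit_full_and_compare(
                table, spec, term, inclusion_term=inclusion
            )
        except ValueError as err:
            logger.warning("model %s ~ %s skipped: %s", spec.outcome, term, err)
            rows.append(
                {"outcome": spec.outcome, "term": term, "error": str(err)}
            )
            continue
        rows.append(
            {
                "outcome": spec.outcome,
                "term": term,
                "family": spec.family,
                "n": full_fit.n_obs,
                "wald_stat": cmp.wald_stat,
                "wald_p": cmp.wald_p,
                "lrt_stat": cmp.lrt_stat,
                "lrt_p": cmp.lrt_p,
                "delta_aic": cmp.delta_aic,
                "error": None,
            }
        )
        reports.append(fit_report(full_fit, cmp))
    if outdir is not None and reports:
        (outdir / "model_reports.txt").write_text("\n\n".join(reports) + "\n")
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline run -> %s (seed %d)", outdir, config.seed)

    roster, events_df, trials, lesions = _load_inputs(config)
    roster.to_csv(outdir / "roster.csv", index=False)
    events_df.to_csv(outdir / "events.csv", index=False)
    if len(trials):
        trials.to_csv(outdir / "trials.csv", index=False)
    if len(lesions):
        lesions.to_csv(outdir / "lesions.csv", index=False)

    centrality = analyse_networks(
        roster,
        events_df,
        net_types=config.networks,
        outdir=outdir,
        observation_window_s=config.observation_window_s,
    )
    centrality.to_csv(outdir / "centrality.csv", index=False)

    screen = redundancy_screen(centrality)
    screen.to_csv(outdir / "redundancy_screen.csv", index=False)

    table = assemble_analysis_table(roster, centrality, trials, lesions)
    table.to_csv(outdir / "analysis_table.csv", index=False)

    models = run_models(table, config.model_grid, outdir=outdir)
    models.to_csv(outdir / "model_comparisons.csv", index=False)

    outputs = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    config_doc = json.dumps(config.to_mapping(), sort_keys=True)
    manifest = {
        "pignet_version": __version__,
        "seed": config.seed,
        "config": config.to_mapping(),
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
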