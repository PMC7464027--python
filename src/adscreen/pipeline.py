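"""Desk-scale orchestration of the screening cascade.

The funnel mirrors a virtual-screening campaign: combinatorial enumeration
-> Lipinski gate -> externally supplied pharmacophore hit list (pure id
membership; the pharmacophore search itself is an external tool) -> full
drug-likeness panel -> QSAR pIC50 prediction -> ranking.  Every stage logs
entering/surviving counts, the run is deterministic given config + seed,
and docking or other external scores can be joined onto the result without
being computed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .chem_io import MoleculeRecord
from .combigen import LibrarySpec, enumerate_library, load_fragment_csv
from .descriptors import descriptor_vector
from .filters import RULE_NAMES, cascade
from .qsar import QSARModel, load_models, load_shipped_models, predict

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ScreenConfig:
    """Everything one screening run needs, loadable from YAML."""

    scaffolds_csv: str | None = None
    rgroups_csv: str | None = None
    molecules: Sequence[MoleculeRecord] | None = None  # alternative direct input
    min_substituents: int = 1
    deduplicate: bool = True
    max_products: int | None = None
    filter_stages: Sequence[str] = field(default_factory=lambda: list(RULE_NAMES))
    hit_list_path: str | None = None
    model_names: Sequence[str] = ("AF", "BF")
    model_file: str | None = None
    primary_target: str = "AChE"
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**data)
        for p in (cfg.scaffolds_csv, cfg.rgroups_csv, cfg.hit_list_path, cfg.model_file):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg


@dataclass
class ScreenResult:
    table: pd.DataFrame           # id, smiles, stage flags, predictions, rank
    funnel: list[dict]            # per stage: {stage, entering, surviving}
    config: dict
    unmatched_scores: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def funnel_json(self) -> str:
        return json.dumps(self.funnel, indent=2)


def _load_models_for(config: ScreenConfig) -> dict[str, QSARModel]:
    pool = load_models(config.model_file) if config.model_file else load_shipped_models()
    missing = [m for m in config.model_names if m not in pool]
    if missing:
        raise StageError(f"stage 'models': unknown model(s) {missing}")
    models = {m: pool[m] for m in config.model_names}
    if not models:
        raise StageError("stage 'models': at least one QSAR model is required")
    return models


def run_screen(config: ScreenConfig) -> ScreenResult:
    """Run the full cascade and return the ranked screen table.

    Ranking is by descending predicted pIC50 on the primary target, with
    the other target's prediction then the compound id as tie-breaks.
    Compounds eliminated upstream keep their stage flags but carry no
    predictions and rank after all survivors.
    """
    models = _load_models_for(config)
    funnel: list[dict] = []

    # stage: enumerate (or accept molecules directly)
    if config.molecules is not None:
        mols = list(config.molecules)
    elif config.scaffolds_csv and config.rgroups_csv:
        spec = LibrarySpec(
            scaffolds=load_fragment_csv(config.scaffolds_csv, "scaffold"),
            rgroups=load_fragment_csv(config.rgroups_csv, "rgroup"),
            min_substituents=config.min_substituents,
            deduplicate=config.deduplicate,
        )
        stream = enumerate_library(spec, strict=config.strict)
        mols = []
        for rec in stream:
            mols.append(rec)
            if config.max_products is not None and len(mols) >= config.max_products:
                break
    else:
        raise StageError("stage 'enumerate': no molecule source configured")
    if len({m.id for m in mols}) != len(mols):
        raise StageError("stage 'enumerate': duplicate molecule ids")
    funnel.append({"stage": "enumerate", "entering": len(mols), "surviving": len(mols)})

    flags = pd.DataFrame(index=[m.id for m in mols])
    flags["smiles"] = [m.smiles for m in mols]
    survivors = mols

    # stage: pharmacophore hit-list gate (optional, pure id membership)
    if config.hit_list_path is not None:
        hit_ids = {
            line.strip()
            for line in Path(config.hit_list_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        entering = len(survivors)
        keep = [m for m in survivors if m.id in hit_ids]
        flags["pharmacophore"] = [m.id in hit_ids for m in mols]
        survivors = keep
        funnel.append(
            {"stage": "pharmacophore", "entering": entering, "surviving": len(survivors)}
        )

    # stage: drug-likeness cascade
    if config.filter_stages:
        try:
            result = cascade(survivors, list(config.filter_stages))
        except Exception as exc:
            raise StageError(f"stage 'filters': {exc}") from exc
        for stage in config.filter_stages:
            flags[f"pass_{stage}"] = [
                (m.id in result.reports) and result.reports[m.id].results[stage].passed
                for m in mols
            ]
        for entry in result.stage_counts:
            funnel.append(
                {
                    "stage": entry["rule"],
                    "entering": entry["entering"],
                    "surviving": entry["surviving"],
                }
            )
        survivors = result.survivors

    # stage: QSAR prediction on survivors
    needed = sorted({t for m in models.values() for t in m.descriptor_names})
    predictions: dict[str, dict[str, float]] = {name: {} for name in models}
    for rec in survivors:
        try:
            d = descriptor_vector(rec, needed)
        except Exception as exc:
            raise StageError(f"stage 'qsar' on {rec.id}: {exc}") from exc
        for name, model in models.items():
            predictions[name][rec.id] = predict(model, d)
    for name, model in models.items():
        flags[f"pIC50_{name}"] = [predictions[name].get(m.id) for m in mols]
    funnel.append({"stage": "qsar", "entering": len(survivors), "surviving": len(survivors)})

    # ranking: primary target first, secondary as tie-break, id as final tie
    primary = [n for n, m in models.items() if m.target == config.primary_target]
    if not primary:
        primary = list(models)
    secondary = [n for n in models if n not in primary]
    sort_cols = [f"pIC50_{primary[0]}"] + [f"pIC50_{s}" for s in secondary[:1]]
    table = flags.reset_index(names="id")
    table = table.sort_values(
        by=sort_cols + ["id"],
        ascending=[False] * len(sort_cols) + [True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table.index + 1

    cfg_echo = {
        k: (list(v) if isinstance(v, (tuple, list)) else v)
        for k, v in vars(config).items()
        if k != "molecules"
    }
    return ScreenResult(
        table=table,
        funnel=funnel,
        config=cfg_echo,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def join_external_scores(result: ScreenResult, scores: pd.DataFrame) -> ScreenResult:
    """Left-join externally computed per-compound scores (e.g. docking).

    ``scores`` must carry an ``id`` column with unique values; compounds
    without a score are flagged in ``unmatched_scores``, never dropped.
    Re-joining the same frame is idempotent (columns are overwritten).
    """
    if "id" not in scores.columns:
        raise ValueError("score table needs an 'id' column")
    if scores["id"].duplicated().any():
        dupes = scores.loc[scores["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in score table: {dupes}")
    if scores.shape[1] < 2 or len(scores) == 0:
        logger.warning("empty score table: result unchanged")
        return result
    table = result.table.drop(
        columns=[c for c in scores.columns if c != "id" and c in result.table.columns]
    )
    merged = table.merge(scores, on="id", how="left", validate="one_to_one")
    matched = set(scores["id"])
    unmatched = [i for i in merged["id"] if i not in matched]
    return ScreenResult(
        table=merged,
        funnel=result.funnel,
        config=result.config,
        unmatched_scores=unmatched,
        version=result.version,
        timestamp=result.timestamp,
    )
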