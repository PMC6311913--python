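"""End-to-end orchestration: extract -> rank -> IFS -> evaluate.

Feature extraction concatenates, per sequence, the enabled blocks in the
frozen order ``psi.*`` (87), ``net.*`` (24), ``hht.*`` (480) — 591 columns
with everything on. Missing structures fall back to the base-pair
maximisation folder and missing profiles to a one-hot pseudo-profile unless
those fallbacks are disabled, in which case extraction fails loudly.

Every artifact a run writes carries the run's config hash and seed, so a
rerun from the same manifest is bit-identical and tables from different
schemas cannot be mixed silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import Metrics, SvmConfig, jackknife
from .hht_features import HHT_FEATURE_NAMES, hht_block, load_property_table
from .io_formats import (
    DotBracket,
    FeatureTable,
    PSSM,
    RnaRecord,
    read_dotbracket,
    read_fasta,
    read_labels,
    read_pssm,
    write_feature_table,
)
from .profile_features import PROFILE_FEATURE_NAMES, profile_block, pseudo_pssm
from .selection import IFSCurve, RankedFeatureList, ifs_select, mrmr_rank
from .structure_features import NETWORK_FEATURE_NAMES, fold_fallback, build_graph, network_block

logger = logging.getLogger(__name__)

ALL_BLOCKS = ("psi", "net", "hht")
BLOCK_NAMES = {
    "psi": PROFILE_FEATURE_NAMES,
    "net": NETWORK_FEATURE_NAMES,
    "hht": HHT_FEATURE_NAMES,
}


@dataclass
class RunConfig:
    """Inputs, enabled blocks and options for one pipeline run."""

    fasta: Path | None = None
    structures: Path | None = None
    pssm_dir: Path | None = None
    labels: Path | None = None
    blocks: tuple[str, ...] = ALL_BLOCKS
    allow_fold_fallback: bool = True
    allow_pseudo_pssm: bool = True
    property_table: Path | None = None
    ifs_step: int = 1
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0
    out_dir: Path = Path("stemloop_run")

    def __post_init__(self) -> None:
        bad = set(self.blocks) - set(ALL_BLOCKS)
        if bad or not self.blocks:
            raise ValueError(f"blocks must be a non-empty subset of {ALL_BLOCKS}")

    def config_hash(self) -> str:
        payload = {
            "blocks": list(self.blocks),
            "svm": [self.svm.C, self.svm.gamma, self.svm.scale],
            "ifs_step": self.ifs_step,
            "seed": self.seed,
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def feature_names_for(blocks: tuple[str, ...]) -> list[str]:
    return [name for b in ALL_BLOCKS if b in blocks for name in BLOCK_NAMES[b]]


def extract_features(
    records: list[RnaRecord],
    structures: dict[str, DotBracket] | None = None,
    pssms: dict[str, PSSM] | None = None,
    blocks: tuple[str, ...] = ALL_BLOCKS,
    labels: pd.Series | None = None,
    allow_fold_fallback: bool = True,
    allow_pseudo_pssm: bool = True,
    property_table: pd.DataFrame | None = None,
) -> FeatureTable:
    """Per-sequence concatenation of the enabled feature blocks."""
    structures = structures or {}
    pssms = pssms or {}
    if "hht" in blocks and property_table is None:
        property_table = load_property_table()
    rows = []
    for rec in records:
        parts = []
        if "psi" in blocks:
            pssm = pssms.get(rec.id)
            if pssm is None:
                if not allow_pseudo_pssm:
                    raise ValueError(f"no PSSM for {rec.id!r} and pseudo-PSSM disabled")
                logger.info("no PSSM for %s; synthesising one-hot pseudo-profile", rec.id)
                pssm = pseudo_pssm(rec)
            parts.append(profile_block(pssm))
        if "net" in blocks:
            db = structures.get(rec.id)
            if db is None:
                if not allow_fold_fallback:
                    raise ValueError(f"no structure for {rec.id!r} and fallback disabled")
                logger.info("no structure for %s; using fallback fold", rec.id)
                db = fold_fallback(rec)
            parts.append(network_block(build_graph(rec, db)))
        if "hht" in blocks:
            parts.append(hht_block(rec, property_table))
        rows.append(np.concatenate(parts))
    values = pd.DataFrame(
        rows, index=[r.id for r in records], columns=feature_names_for(blocks)
    )
    if labels is not None:
        labels = labels.reindex(values.index)
        if labels.isna().any():
            raise ValueError("labels missing for some extracted records")
        labels = labels.astype(int)
    return FeatureTable(values, labels)


def load_inputs(run: RunConfig) -> tuple[list[RnaRecord], dict, dict, pd.Series | None]:
    if run.fasta is None:
        raise ValueError("a FASTA input is required")
    records = read_fasta(run.fasta)
    structures: dict[str, DotBracket] = {}
    if run.structures is not None:
        for rec, db in read_dotbracket(run.structures):
            structures[rec.id] = db
    pssms: dict[str, PSSM] = {}
    if run.pssm_dir is not None:
        for rec in records:
            for suffix in (".tsv", ".pssm", ".txt"):
                p = Path(run.pssm_dir) / f"{rec.id}{suffix}"
                if p.exists():
                    pssms[rec.id] = read_pssm(p, rec_id=rec.id)
                    break
    labels = read_labels(run.labels) if run.labels is not None else None
    return records, structures, pssms, labels


def extract(run: RunConfig) -> FeatureTable:
    records, structures, pssms, labels = load_inputs(run)
    table = load_property_table(run.property_table) if "hht" in run.blocks else None
    return extract_features(
        records,
        structures,
        pssms,
        blocks=run.blocks,
        labels=labels,
        allow_fold_fallback=run.allow_fold_fallback,
        allow_pseudo_pssm=run.allow_pseudo_pssm,
        property_table=table,
    )


@dataclass
class RunReport:
    table: FeatureTable
    ranking: RankedFeatureList
    curve: IFSCurve
    metrics: Metrics
    manifest: dict


def run_all(run: RunConfig) -> RunReport:
    """Extraction -> mRMR ranking -> IFS -> jackknife at the optimal prefix.

    Writes the feature table, ranking, IFS curve, metrics and a
    machine-readable manifest under ``run.out_dir``.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("extracting features (blocks=%s)", ",".join(run.blocks))
    table = extract(run)
    if table.labels is None:
        raise ValueError("run-all requires labels")
    write_feature_table(table, out / "features.tsv")

    logger.info("ranking %d features by mRMR", len(table.feature_names))
    ranking = mrmr_rank(table)
    ranking.to_frame().to_csv(out / "ranking.tsv", sep="\t")

    logger.info("incremental feature selection (step=%d)", run.ifs_step)
    curve = ifs_select(table, ranking, run.svm, step=run.ifs_step)
    curve.to_frame().to_csv(out / "ifs_curve.tsv", sep="\t")

    best = FeatureTable(
        table.values[ranking.names[: curve.optimal_k]], table.labels
    )
    metrics = jackknife(best, run.svm)
    pd.DataFrame([metrics.__dict__]).to_csv(out / "metrics.tsv", sep="\t", index=False)

    manifest = {
        "stemloop_version": __version__,
        "numpy_version": np.__version__,
        "seed": run.seed,
        "config_hash": run.config_hash(),
        "blocks": list(run.blocks),
        "n_records": len(table),
        "n_features": len(table.feature_names),
        "optimal_k": curve.optimal_k,
        "svm": {"C": run.svm.C, "gamma": run.svm.gamma, "scale": run.svm.scale},
        "metrics": {
            "sn": metrics.sn, "sp": metrics.sp,
            "acc": metrics.acc, "mcc": metrics.mcc,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "done: acc=%.4f mcc=%.4f at k=%d", metrics.acc, metrics.mcc, curve.optimal_k
    )
    return RunReport(table, ranking, curve, metrics, manifest)
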