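"""Dataset CSV reading/writing, deduplication and the end-to-end pipeline.

The canonical dialect is a comma-separated, UTF-8 file with a header row and
columns ``sequence``, ``charge``, ``ccs`` (optional for prediction-only
input) and optional ``source``.  Column aliases used by published CCS dumps
(e.g. ``Modified sequence``, ``Charge``, ``CCS``) are accepted; rows with an
unparsable sequence or an unsupported charge state are dropped and the drop
count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import Peptide, parse_peptide
from .errors import DatasetFormatError, PepCCSError
from .features import EncodedDataset, FeaturizationConfig, encode_peptides
from .metrics import evaluate, evaluate_by_ccs_range, evaluate_by_group
from .model import (
    NetworkConfig,
    TrainingConfig,
    build_network,
    predict,
    train,
)
from .simulate import DatasetSplits, GeneratorConfig, GroundTruthParams, make_dataset

logger = logging.getLogger("pepccs")

#: accepted (lower-cased, stripped) header names for each canonical column
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "sequence": ("sequence", "modified sequence", "modified_sequence", "seq", "peptide"),
    "charge": ("charge", "z", "charge state", "charge_state"),
    "ccs": ("ccs", "ccs_a2", "ccs (a2)", "ccs_value"),
    "source": ("source", "origin", "organism", "subset"),
}


@dataclass(frozen=True)
class DatasetRecord:
    sequence: str  # modified-sequence string (any accepted dialect)
    charge: int
    ccs: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.ccs is not None and self.ccs <= 0:
            raise DatasetFormatError(f"non-positive CCS for {self.sequence!r}")


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    lowered = {c.strip().lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
    for mandatory in ("sequence", "charge"):
        if mandatory not in resolved:
            raise DatasetFormatError(f"no column found for {mandatory!r} in {columns}")
    return resolved


def read_dataset(path: str | Path) -> list[DatasetRecord]:
    """Read records, dropping (and logging) rows the parser rejects."""
    df = pd.read_csv(path)
    cols = _resolve_columns(list(df.columns))
    df = df.rename(columns={v: k for k, v in cols.items()})[list(cols)]
    records: list[DatasetRecord] = []
    dropped = 0
    for row in df.to_dict("records"):
        seq = str(row["sequence"])
        try:
            charge = int(row["charge"])
            parse_peptide(seq, charge)  # validation only
            ccs = None
            if "ccs" in cols:
                raw = row["ccs"]
                ccs = None if pd.isna(raw) else float(raw)
            source = str(row["source"]) if "source" in cols else None
            records.append(DatasetRecord(seq, charge, ccs, source))
        except (PepCCSError, ValueError):
            dropped += 1
    if dropped:
        logger.info("read_dataset: dropped %d invalid row(s) from %s", dropped, path)
    logger.info("read_dataset: %d record(s) kept from %s", len(records), path)
    return records


def write_dataset(records: list[DatasetRecord], path: str | Path) -> None:
    """Write the canonical CSV dialect."""
    rows = {
        "sequence": [r.sequence for r in records],
        "charge": [r.charge for r in records],
    }
    if any(r.ccs is not None for r in records):
        rows["ccs"] = [r.ccs for r in records]
    if any(r.source is not None for r in records):
        rows["source"] = [r.source for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_peptides(records: list[DatasetRecord]) -> list[Peptide]:
    return [parse_peptide(r.sequence, r.charge) for r in records]


def splits_to_records(splits: DatasetSplits) -> dict[str, list[DatasetRecord]]:
    out = {}
    for name in ("train", "val", "test"):
        ls = getattr(splits, name)
        out[name] = [
            DatasetRecord(p.sequence, p.charge, float(c))
            for p, c in zip(ls.peptides, ls.ccs)
        ]
    return out


def deduplicate_against(
    train: list[DatasetRecord], holdout: list[DatasetRecord]
) -> list[DatasetRecord]:
    """Drop training records whose (sequence, charge) occurs in the holdout."""
    held = {
        (parse_peptide(r.sequence, r.charge).sequence, r.charge) for r in holdout
    }
    kept = [
        r
        for r in train
        if (parse_peptide(r.sequence, r.charge).sequence, r.charge) not in held
    ]
    removed = len(train) - len(kept)
    if removed:
        logger.info("deduplicate_against: removed %d overlapping record(s)", removed)
    return kept


@dataclass
class RunConfig:
    """Configuration of the end-to-end synthetic-data pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ground_truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    features: FeaturizationConfig = field(default_factory=FeaturizationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if (self.network.variant == "reduced") != self.features.reduced:
            raise DatasetFormatError(
                "network variant and featurization reduced flag must agree"
            )


def _encode_split(ls, cfg: FeaturizationConfig) -> EncodedDataset:
    return encode_peptides(ls.peptides, cfg, ccs=ls.ccs)


def report_frame(pred: np.ndarray, ref: np.ndarray, charges: np.ndarray) -> pd.DataFrame:
    """Overall, per-charge and per-CCS-range evaluation rows."""
    rows = [{"subset": "overall", **evaluate(pred, ref).as_dict()}]
    for z, rep in evaluate_by_group(pred, ref, charges).items():
        rows.append({"subset": f"charge_{z}", **rep.as_dict()})
    for rng_label, rep in evaluate_by_ccs_range(pred, ref).items():
        rows.append({"subset": f"ccs_{rng_label}", **rep.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate, featurize, train, evaluate; write model, history and report.

    Returns the paths of the three artifacts.  Fully reproducible from the
    generator and training seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline: generating %d peptides", cfg.generator.n_peptides)
    splits = make_dataset(cfg.generator, cfg.ground_truth)
    logger.info(
        "pipeline: split sizes train=%d val=%d test=%d",
        len(splits.train), len(splits.val), len(splits.test),
    )
    enc_train = _encode_split(splits.train, cfg.features)
    enc_val = _encode_split(splits.val, cfg.features)
    enc_test = _encode_split(splits.test, cfg.features)

    net = build_network(cfg.network, cfg.features.L, cfg.features.global_dim)
    model = train(net, enc_train, enc_val, cfg.training)

    model_path = out / "model.npz"
    model.save(str(model_path))
    history_path = out / "history.csv"
    pd.DataFrame(model.history, columns=["iteration", "val_mae_a2"]).to_csv(
        history_path, index=False
    )
    pred = predict(model, enc_test)
    report = report_frame(pred, enc_test.ccs, enc_test.charges)
    report_path = out / "report.csv"
    report.to_csv(report_path, index=False, float_format="%.6g")
    logger.info("pipeline: artifacts written to %s", out)
    return {"model": model_path, "history": history_path, "report": report_path}
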