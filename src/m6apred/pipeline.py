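"""Experiment orchestration: grid CV runs, tuning, and transfer testing.

A run is described by a :class:`RunConfig` (input FASTA pair or a fixture
config, a scheme selection, model requests, folds, seed, output directory).
Each (scheme, model) cell produces one ``EvaluationReport`` JSON; every run
appends rows to a flat ``summary.csv`` and writes a ``manifest.json`` echoing
the configuration so outputs are regenerable bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .encoders import EncodingScheme, enumerate_schemes
from .errors import ConfigError, M6aPredError
from .evaluation import METRIC_NAMES, EvaluationReport, cross_species, cross_validate
from .fixtures import FixtureConfig, generate_benchmark
from .modeling import FAMILIES, make_spec, randomized_search
from .seqio import SequenceRecord, read_fasta, validate_benchmark

SUMMARY_COLUMNS = [
    "species", "scheme", "param", "model", "tuned", "protocol",
    "acc", "sens", "spec", "mcc", "auc", "seed",
]


@dataclass(frozen=True)
class ModelRequest:
    """One classifier to run: mode is 'default', 'tuned', or 'search'."""

    family: str
    mode: str = "default"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.mode not in ("default", "tuned", "search"):
            raise ConfigError(f"unknown model mode {self.mode!r}")


@dataclass
class RunConfig:
    """Inputs and grid selection for one experiment run."""

    pos_fasta: str | None = None
    neg_fasta: str | None = None
    fixture: FixtureConfig | None = None
    schemes: str | Sequence[str] = "grid15"
    models: Sequence[ModelRequest] = (ModelRequest("random_forest", "default"),)
    k: int = 5
    seed: int = 0
    outdir: str = "results"
    species: str = ""
    expected_length: int | None = None
    require_center_A: bool = False
    search_iters: int = 25

    def validate(self) -> None:
        has_files = self.pos_fasta is not None and self.neg_fasta is not None
        has_fixture = self.fixture is not None
        if has_files == has_fixture:
            raise ConfigError("exactly one input source required: FASTA pair xor fixture")
        if self.k < 2:
            raise ConfigError("k must be >= 2")

    def resolve_schemes(self) -> list[EncodingScheme]:
        if self.schemes == "grid15":
            return enumerate_schemes()
        return [EncodingScheme.from_name(n) for n in self.schemes]

    def load_records(self) -> list[SequenceRecord]:
        if self.fixture is not None:
            return generate_benchmark(self.fixture)
        pos = read_fasta(self.pos_fasta, label=1, species=self.species)
        neg = read_fasta(self.neg_fasta, label=0, species=self.species)
        return pos + neg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.fixture is not None:
            d["fixture"] = dataclasses.asdict(self.fixture)
        d["models"] = [dataclasses.asdict(m) for m in self.models]
        d["schemes"] = (
            self.schemes if isinstance(self.schemes, str) else list(self.schemes)
        )
        return d


def _write_summary(rows: list[dict], path: Path) -> None:
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    for m in METRIC_NAMES:
        df[m] = df[m].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def _manifest(config_echo: dict, seed: int, cells: list[dict]) -> dict:
    return {
        "seed": seed,
        "config": config_echo,
        "versions": {
            "m6apred": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "cells": cells,
    }


def _resolve_spec(request: ModelRequest, X_records, scheme, config: RunConfig):
    """Materialize a ModelSpec for one cell, running the search if asked."""
    if request.mode == "search":
        from .encoders import encode_dataset

        X = encode_dataset(X_records, scheme)
        best, _table = randomized_search(
            request.family, X, n_iter=config.search_iters,
            seed=config.seed, folds=config.k,
        )
        return best
    return make_spec(request.family, tuned=(request.mode == "tuned"), seed=config.seed)


def run_experiment(config: RunConfig) -> list[Path]:
    """Run the requested (scheme x model) grid under stratified k-fold CV.

    Writes one report JSON per cell, a ``summary.csv``, and a
    ``manifest.json``; per-cell failures are recorded in the manifest without
    aborting the remaining cells. Returns the written report paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = config.load_records()
    validate_benchmark(
        records,
        expected_length=config.expected_length,
        require_center_A=config.require_center_A,
    )
    species = config.species or (records[0].species if records else "")
    rows: list[dict] = []
    cells: list[dict] = []
    written: list[Path] = []
    for scheme in config.resolve_schemes():
        for request in config.models:
            cell = f"{scheme.name}_{request.family}_{request.mode}"
            try:
                spec = _resolve_spec(request, records, scheme, config)
                report = cross_validate(
                    records, scheme, spec, k=config.k, seed=config.seed
                )
            except M6aPredError as exc:
                cells.append({"cell": cell, "status": "failed", "error": str(exc)})
                continue
            path = outdir / f"report_{cell}.json"
            path.write_text(report.to_json())
            written.append(path)
            rows.append(report.csv_row(species=species))
            cells.append({"cell": cell, "status": "ok"})
    _write_summary(rows, outdir / "summary.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(_manifest(config.as_dict(), config.seed, cells), indent=2)
    )
    return written


def run_transfer(
    train_config: RunConfig, test_config: RunConfig
) -> list[Path]:
    """Cross-species protocol: for each scheme, fit on the train species and
    test on the test species, then run within-species CV on the test species
    for juxtaposition. The summary gains a ``transfer_minus_cv`` accuracy
    column per scheme.
    """
    train_config.validate()
    test_config.validate()
    outdir = Path(train_config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    train_records = train_config.load_records()
    test_records = test_config.load_records()
    rows: list[dict] = []
    extra: list[dict] = []
    cells: list[dict] = []
    written: list[Path] = []
    train_species = train_config.species or train_records[0].species
    test_species = test_config.species or test_records[0].species
    for scheme in train_config.resolve_schemes():
        for request in train_config.models:
            cell = f"{scheme.name}_{request.family}_{request.mode}"
            try:
                spec = _resolve_spec(request, train_records, scheme, train_config)
                transfer = cross_species(train_records, test_records, scheme, spec)
                within = cross_validate(
                    test_records, scheme, spec,
                    k=test_config.k, seed=test_config.seed,
                )
            except M6aPredError as exc:
                cells.append({"cell": cell, "status": "failed", "error": str(exc)})
                continue
            tpath = outdir / f"transfer_{cell}.json"
            tpath.write_text(transfer.to_json())
            wpath = outdir / f"withincv_{cell}.json"
            wpath.write_text(within.to_json())
            written += [tpath, wpath]
            rows.append(transfer.csv_row(species=f"{train_species}->{test_species}"))
            rows.append(within.csv_row(species=test_species))
            extra.append(
                {
                    "cell": cell,
                    "transfer_acc": transfer.aggregate["acc"],
                    "cv_acc": within.aggregate["acc"],
                    "transfer_minus_cv": transfer.aggregate["acc"]
                    - within.aggregate["acc"],
                }
            )
            cells.append({"cell": cell, "status": "ok"})
    _write_summary(rows, outdir / "summary.csv")
    juxt = pd.DataFrame(
        extra, columns=["cell", "transfer_acc", "cv_acc", "transfer_minus_cv"]
    )
    for c in ("transfer_acc", "cv_acc", "transfer_minus_cv"):
        juxt[c] = juxt[c].map(lambda v: f"{v:.6f}")
    juxt.to_csv(outdir / "juxtaposition.csv", index=False)
    manifest = _manifest(
        {"train": train_config.as_dict(), "test": test_config.as_dict()},
        train_config.seed,
        cells,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return written
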