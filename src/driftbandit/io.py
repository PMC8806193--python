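"""TSV schemas and seeded-stream plumbing shared across the pipeline.

All behavioural times are seconds; pupil timestamps are milliseconds.
Sessions and posterior draws travel as tab-separated text with strict
header validation, so every artifact is diffable and round-trips to full
precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._mcmc import SamplerSettings
from .linking import PosteriorSet
from .task_env import SESSION_COLUMNS

PLAUSIBLE_RT_MAX_S = 100.0  # beyond this an RT column smells of milliseconds


class SchemaError(ValueError):
    """A file's columns do not match the declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def write_session(session: pd.DataFrame, path: str | Path) -> None:
    _check_columns(session, SESSION_COLUMNS, "session")
    session.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_session(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path}: empty file")
    _check_columns(df, SESSION_COLUMNS, str(path))
    rt = df["rt"].dropna()
    if len(rt) and rt.max() > PLAUSIBLE_RT_MAX_S:
        warnings.warn(
            f"{path}: RT values up to {rt.max():g} look like milliseconds; "
            "the schema expects seconds"
        )
    return df


def write_posteriors(posterior: PosteriorSet, path: str | Path) -> None:
    df = pd.DataFrame(posterior.draws, columns=posterior.param_names)
    df["log_likelihood"] = posterior.loglik
    header = (
        f"# n_samples={posterior.settings.n_samples} "
        f"burn={posterior.settings.burn} thin={posterior.settings.thin}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_posteriors(path: str | Path) -> PosteriorSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: missing sampler-settings header line")
        settings = dict(
            kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
        )
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if "log_likelihood" not in df.columns:
        raise SchemaError(f"{path}: missing log_likelihood column")
    names = [c for c in df.columns if c != "log_likelihood"]
    return PosteriorSet(
        param_names=names,
        draws=df[names].to_numpy(),
        loglik=df["log_likelihood"].to_numpy(),
        settings=SamplerSettings(
            n_samples=int(settings["n_samples"]),
            burn=int(settings["burn"]),
            thin=int(settings["thin"]),
        ),
        accept_rate=np.full(len(names), np.nan),
    )


def seed_streams(master_seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named independent RNG substreams derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}
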