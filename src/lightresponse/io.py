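"""Delimited-text input/output and run configuration.

The dataset dialect is comma-separated with header columns
``treatment, replicate, intensity, response, response_kind`` — the same
dialect the simulator writes and the fitter reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import FitConfig, PosteriorChain

DATASET_COLUMNS = ("treatment", "replicate", "intensity", "response", "response_kind")
VALID_KINDS = ("phi_ii", "tef", "npq")


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad_kinds = set(df["response_kind"]) - set(VALID_KINDS)
    if bad_kinds:
        raise SchemaError(f"unknown response_kind value(s): {sorted(bad_kinds)}")
    if not np.all(np.isfinite(df["response"])) or not np.all(np.isfinite(df["intensity"])):
        raise SchemaError("non-finite intensity or response values")
    phi = df.loc[df["response_kind"] == "phi_ii", "response"]
    if len(phi) and (phi.min() < 0 or phi.max() > 1):
        raise SchemaError("phi_ii responses must lie in [0, 1]")
    return df


def read_dataset(path) -> pd.DataFrame:
    return validate_dataset(pd.read_csv(path))


def write_dataset(df: pd.DataFrame, path) -> None:
    validate_dataset(df).to_csv(path, index=False)


def write_chain(chain: PosteriorChain, path) -> None:
    """Posterior draws as a columnar table (log-scale columns, plus header
    metadata rows encoded as comment lines)."""
    path = Path(path)
    meta = (
        f"# kind={chain.kind} acceptance_rate={chain.acceptance_rate:.6f} "
        f"seed={chain.seed} a_ii={chain.a_ii}\n"
    )
    with open(path, "w") as fh:
        fh.write(meta)
        pd.DataFrame(chain.draws, columns=list(chain.param_names)).to_csv(fh, index=False)


def read_chain(path) -> PosteriorChain:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return PosteriorChain(
        kind=meta["kind"],
        param_names=tuple(df.columns),
        draws=df.to_numpy(),
        acceptance_rate=float(meta["acceptance_rate"]),
        seed=seed,
        a_ii=float(meta.get("a_ii", 0.42)),
    )


@dataclass
class RunConfig:
    """Batch-run configuration (YAML-serialisable)."""

    input: str | None = None
    response_kind: str = "phi_ii"
    fit: FitConfig = field(default_factory=FitConfig)
    comparisons: list[dict] = field(default_factory=list)  # {a, b, parameter}
    output_dir: str = "results"
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit = FitConfig(**raw.pop("fit", {}))
        return cls(fit=fit, **raw)

    def to_yaml(self, path) -> None:
        raw = {
            "input": self.input,
            "response_kind": self.response_kind,
            "fit": {
                "n_samples": self.fit.n_samples,
                "burn_in": self.fit.burn_in,
                "n_chains": self.fit.n_chains,
                "seed": self.fit.seed,
                "proposal_scale": self.fit.proposal_scale,
                "a_ii": self.fit.a_ii,
            },
            "comparisons": self.comparisons,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }
        Path(path).write_text(yaml.safe_dump(raw))
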