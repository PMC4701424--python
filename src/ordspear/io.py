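"""File formats, experiment configs, fixtures, and run manifests.

All formats are plain text: contingency tables and paired data as
CSV/TSV, experiment configuration as TOML, results as tidy CSV plus JSON,
and a JSON manifest recording everything needed to re-execute a run.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountTable, PairedSample, ProbabilityTable
from .errors import ValidationError
from .simulation import (
    PRESET_MARGIN_P,
    PRESET_MARGIN_Q,
    CopulaScenario,
    McConfig,
)

__all__ = [
    "RunManifest",
    "read_table",
    "read_pairs",
    "load_experiment_config",
    "make_fixture",
    "package_version",
]


def package_version() -> str:
    try:
        return _pkg_version("ordspear")
    except PackageNotFoundError:  # running from a source tree
        return "0+unknown"


@dataclass(frozen=True)
class RunManifest:
    """Record of one CLI run, sufficient to re-execute it."""

    command: str
    options: dict
    seed: int | None
    version: str = field(default_factory=package_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    input_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "options": self.options,
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "input_digests": self.input_digests,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=False) + "\n"
        )


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_grid(path: str | Path) -> pd.DataFrame:
    """Read a rectangular grid, stripping an optional header row/column."""
    try:
        df = pd.read_csv(path, header=None, sep=None, engine="python",
                         skip_blank_lines=True, dtype=str)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"could not parse {path}: {e}") from e

    def _numeric(s) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if df.shape[0] and not all(_numeric(v) for v in df.iloc[0]):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] and not all(_numeric(v) for v in df.iloc[:, 0]):
        df = df.iloc[:, 1:]
    bad = [(i, j) for i in range(df.shape[0]) for j in range(df.shape[1])
           if not _numeric(df.iat[i, j])]
    if bad:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at line {i + 1}, "
            f"column {j + 1} (after header removal)"
        )
    return df.astype(float)


def read_table(
    path: str | Path, kind: str = "auto"
) -> CountTable | ProbabilityTable:
    """Read an I x J contingency table from CSV/TSV.

    ``kind`` is ``"counts"``, ``"probabilities"`` or ``"auto"``: a grid is
    auto-detected as probabilities when it sums to one and contains
    non-integer values, otherwise as counts.
    """
    grid = _read_grid(path).to_numpy()
    if kind not in ("auto", "counts", "probabilities"):
        raise ValidationError(f"unknown table kind {kind!r}")
    if kind == "auto":
        integral = bool(np.all(np.mod(grid, 1) == 0))
        kind = (
            "probabilities"
            if (abs(grid.sum() - 1.0) <= 1e-6 and not integral)
            else "counts"
        )
    if kind == "probabilities":
        return ProbabilityTable(grid)
    return CountTable(grid)


def read_pairs(
    path: str | Path,
    levels_x: int | None = None,
    levels_y: int | None = None,
) -> PairedSample:
    """Read paired ordinal observations: two columns of integer codes."""
    grid = _read_grid(path)
    if grid.shape[1] != 2:
        raise ValidationError(
            f"{path}: paired data needs exactly 2 columns, got {grid.shape[1]}"
        )
    x = grid.iloc[:, 0].to_numpy()
    y = grid.iloc[:, 1].to_numpy()
    if not np.all(np.mod(x, 1) == 0) or not np.all(np.mod(y, 1) == 0):
        raise ValidationError(f"{path}: category codes must be integers")
    return PairedSample(
        x=x.astype(int), y=y.astype(int),
        levels_x=levels_x or 0, levels_y=levels_y or 0,
    )


_SCENARIO_KEYS = {"latent_corr", "margins_p", "margins_q"}
_EXPERIMENT_KEYS = {
    "kind", "null_rho", "sample_sizes", "reps", "alpha", "methods", "seed",
    "bootstrap_reps", "bootstrap_B",
}


def load_experiment_config(path: str | Path) -> tuple[McConfig, str]:
    """Parse a TOML experiment config; returns (config, kind).

    ``kind`` is ``"size"`` or ``"power"``.  Unknown keys are rejected by
    name so typos fail loudly.
    """
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    unknown = set(raw) - {"scenario", "experiment"}
    if unknown:
        raise ValidationError(f"unknown config section {sorted(unknown)[0]!r}")
    scen_raw = raw.get("scenario", {})
    exp_raw = raw.get("experiment", {})
    for section, allowed, got in (
        ("scenario", _SCENARIO_KEYS, scen_raw),
        ("experiment", _EXPERIMENT_KEYS, exp_raw),
    ):
        unknown = set(got) - allowed
        if unknown:
            raise ValidationError(
                f"unknown key {sorted(unknown)[0]!r} in [{section}]"
            )
    if "latent_corr" not in scen_raw:
        raise ValidationError("config [scenario] requires latent_corr")
    scenario = CopulaScenario(
        latent_corr=float(scen_raw["latent_corr"]),
        margins_p=tuple(scen_raw.get("margins_p", PRESET_MARGIN_P)),
        margins_q=tuple(scen_raw.get("margins_q", PRESET_MARGIN_Q)),
    )
    kind = exp_raw.get("kind", "size")
    if kind not in ("size", "power"):
        raise ValidationError(f"experiment kind must be size or power, got {kind!r}")
    config = McConfig(
        scenario=scenario,
        sample_sizes=tuple(exp_raw.get("sample_sizes", (25, 50, 100, 200, 400, 800))),
        reps=int(exp_raw.get("reps", 20000)),
        alpha=float(exp_raw.get("alpha", 0.05)),
        methods=tuple(exp_raw.get("methods", ("asymptotic",))),
        seed=int(exp_raw.get("seed", 0)),
        null_rho=(
            float(exp_raw["null_rho"]) if "null_rho" in exp_raw else None
        ),
        bootstrap_reps=int(exp_raw.get("bootstrap_reps", 2000)),
        bootstrap_B=int(exp_raw.get("bootstrap_B", 400)),
    )
    return config, kind


_FIXTURE_KINDS = ("table-csv", "pairs-csv", "scenario-toml")


def make_fixture(kind: str, seed: int = 0, outdir: str | Path = ".") -> Path:
    """Write a small, syntactically canonical example input file.

    ``table-csv`` includes an empty declared category (a zero row) to
    exercise support declaration; ``pairs-csv`` is a random draw from the
    reference copula design; ``scenario-toml`` is the reference simulation
    design itself.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "table-csv":
        path = outdir / "table.csv"
        counts = np.array([[12, 5, 2], [0, 0, 0], [3, 7, 11]])
        header = "y1,y2,y3"
        lines = [header] + [",".join(str(v) for v in row) for row in counts]
        path.write_text("\n".join(lines) + "\n")
    elif kind == "pairs-csv":
        from .simulation import gaussian_copula_table, sample_pairs

        path = outdir / "pairs.csv"
        table = gaussian_copula_table(CopulaScenario(0.5))
        s = sample_pairs(table, 60, rng)
        lines = ["x,y"] + [f"{a},{b}" for a, b in zip(s.x, s.y)]
        path.write_text("\n".join(lines) + "\n")
    elif kind == "scenario-toml":
        path = outdir / "scenario.toml"
        path.write_text(
            "[scenario]\n"
            "latent_corr = 0.5\n"
            f"margins_p = [{', '.join(str(v) for v in PRESET_MARGIN_P)}]\n"
            f"margins_q = [{', '.join(str(v) for v in PRESET_MARGIN_Q)}]\n"
            "\n"
            "[experiment]\n"
            'kind = "size"\n'
            "sample_sizes = [25, 50, 100, 200, 400, 800]\n"
            "reps = 20000\n"
            "alpha = 0.05\n"
            'methods = ["asymptotic"]\n'
            "seed = 0\n"
        )
    else:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}"
        )
    return path


def eprint(*args) -> None:
    print(*args, file=sys.stderr)
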