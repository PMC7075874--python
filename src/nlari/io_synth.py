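"""Beat-series readers/writers and the synthetic fixture generator.

Synthetic fixtures emulate the study's data shape: 900-point windows of
beat series generated by the NLARI process with a linear log-HR trend,
written as plain RR (seconds) or HR (bpm) text with a JSON manifest of the
true parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .simulate import simulate_nlari

__all__ = ["FixtureSpec", "read_series", "write_series", "make_fixture", "REGIME_PRESETS"]

#: Canonical parameter presets per dynamic regime.  The stable preset uses the
#: printed resistance/noise values (alpha = 0.7786, sigma = 0.0275) with a
#: mid-range restoration coefficient.
REGIME_PRESETS = {
    "stable_fixed_point": ModelParams(omega=1e-4, sigma=0.0275, alpha=0.7786, beta=0.3),
    "near_boundary": ModelParams(omega=1e-4, sigma=0.0275, alpha=0.7786, beta=0.017 * (4 - 2 * 0.7786)),
    "unit_root": ModelParams(omega=0.0, sigma=0.0275, alpha=0.7786, beta=0.0),
    "two_cycle": ModelParams(omega=0.0, sigma=0.005, alpha=0.7786, beta=1.2 * (4 - 2 * 0.7786)),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic beat-series fixture."""

    regime: str | None = "stable_fixed_point"
    params: ModelParams | None = None
    n: int = 900
    x0: float = 4.1
    seed: int = 0
    kind: str = "rr_seconds"
    windows: int = 1

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("fixtures must have n >= 100 points")
        if self.kind not in ("rr_seconds", "hr_bpm"):
            raise ValueError(f"unsupported output kind {self.kind!r}")
        if self.params is None and self.regime not in REGIME_PRESETS:
            raise ValueError(
                f"unknown regime {self.regime!r}; choose from {sorted(REGIME_PRESETS)}"
            )

    def model_params(self) -> ModelParams:
        return self.params if self.params is not None else REGIME_PRESETS[self.regime]


def read_series(path, format: str | None = None, kind: str = "rr_seconds") -> np.ndarray:
    """Read a beat series from plain text (one value per line, '#' comments)
    or CSV (column named rr_s / hr_bpm / value, or the first column).

    Raises a ValueError naming the offending line for unparseable or
    nonpositive entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "txt")
    if fmt == "csv":
        df = pd.read_csv(path, comment="#")
        for col in ("rr_s", "hr_bpm", "value"):
            if col in df.columns:
                values = df[col].to_numpy(dtype=float)
                break
        else:
            values = df.iloc[:, 0].to_numpy(dtype=float)
        bad = np.flatnonzero(~(values > 0))
        if bad.size:
            raise ValueError(f"{path}: nonpositive value at data row {bad[0] + 1}")
        return values
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                v = float(text)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable entry {text!r}") from exc
            if not v > 0:
                raise ValueError(f"{path}:{lineno}: nonpositive beat value {v!r}")
            values.append(v)
    return np.asarray(values, dtype=float)


def write_series(path, values, kind: str = "rr_seconds", header: bool = True) -> None:
    """Write a beat series as plain text at full double precision."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# kind: {kind}\n")
        for v in np.asarray(values, dtype=float):
            fh.write(f"{float(v)!r}\n")


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Generate fixture file(s) plus a JSON manifest of ground truth.

    The simulated log-HR level X is mapped to HR = exp(X) (bpm) and
    RR = 60/HR (s); the same spec always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = spec.model_params()
    files = []
    for w in range(spec.windows):
        sim = simulate_nlari(p, spec.n, x0=spec.x0, seed=spec.seed + w)
        hr = np.exp(sim.x)
        values = 60.0 / hr if spec.kind == "rr_seconds" else hr
        name = f"synthetic_{spec.regime or 'custom'}_w{w}.txt"
        write_series(out_dir / name, values, kind=spec.kind)
        files.append(name)
    manifest = {
        "regime": spec.regime,
        "params": asdict(p),
        "n": spec.n,
        "x0": spec.x0,
        "seed": spec.seed,
        "kind": spec.kind,
        "windows": spec.windows,
        "files": files,
        "synthetic": True,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
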