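"""Run configuration, result tables and calibration plots.

The run configuration is a single YAML or JSON document::

    families: [single, two_both, two_one, differential]
    factors:
      psi_v: [0.0, 0.25]
      theta_v: [0.5, 1.0, 2.0]
      sigma_eps_v: [0.5, 1.0, 2.0]   # noise SDs
      sigma_eps_d: [0.5, 1.0, 2.0]
      rho: [0.0, 0.5, 0.9]
    run:
      n_derivation: 2000
      n_validation: 2000
      replications: 10000
      seed: 1
      workers: 1

Summary tables report calibration-in-the-large on a x10 scale (display
only; the stored values are on the raw logit scale).  The single-predictor
overview table pools the grid cells by the ordering of derivation and
validation noise (less / equally / more precise at validation): each
displayed row is the mean over the (sigma_D, sigma_V) pairs in the block of
the per-pair summary statistic, with the across-pair SD in parentheses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenarios import FAMILIES, GridFactors

__all__ = [
    "RunConfig",
    "default_config",
    "load_config",
    "summaries_to_frame",
    "render_single_predictor_table",
    "render_differential_table",
    "plot_calibration",
]


@dataclass
class RunConfig:
    """Validated simulation-run configuration."""

    families: tuple[str, ...] = FAMILIES
    factors: GridFactors = field(default_factory=GridFactors)
    n_derivation: int = 2000
    n_validation: int = 2000
    replications: int = 10_000
    seed: int = 1
    workers: int = 1

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"config key 'families': unknown family {fam!r}")
        for key in ("n_derivation", "n_validation"):
            if getattr(self, key) < 2:
                raise ValueError(f"config key 'run.{key}': must be >= 2")
        if self.replications < 2:
            raise ValueError("config key 'run.replications': must be >= 2")
        if self.workers < 1:
            raise ValueError("config key 'run.workers': must be >= 1")
        f = self.factors
        for key in ("sigma_eps_v", "sigma_eps_d", "sigma_eps1_d", "sigma_eps1_v"):
            if any(v <= 0 for v in getattr(f, key)):
                raise ValueError(f"config key 'factors.{key}': noise SDs must be > 0")
        if any(t == 0 for t in f.theta_v):
            raise ValueError("config key 'factors.theta_v': theta must be nonzero")
        if any(not (-1.0 < r < 1.0) for r in f.rho):
            raise ValueError("config key 'factors.rho': must lie in (-1, 1)")


def default_config() -> RunConfig:
    """The full 432-scenario study configuration."""
    return RunConfig()


def _as_tuple(x) -> tuple:
    if isinstance(x, (list, tuple)):
        return tuple(x)
    return (x,)


def config_from_dict(doc: dict) -> RunConfig:
    doc = doc or {}
    known = {"families", "factors", "run"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    factor_doc = doc.get("factors", {}) or {}
    valid_factors = set(GridFactors.__dataclass_fields__)
    bad = set(factor_doc) - valid_factors
    if bad:
        raise ValueError(f"unknown config key(s) under 'factors': {sorted(bad)}")
    fkw = {
        k: (_as_tuple(v) if k != "sigma_eps0" else float(v))
        for k, v in factor_doc.items()
    }
    run_doc = doc.get("run", {}) or {}
    valid_run = {"n_derivation", "n_validation", "replications", "seed", "workers"}
    bad = set(run_doc) - valid_run
    if bad:
        raise ValueError(f"unknown config key(s) under 'run': {sorted(bad)}")
    return RunConfig(
        families=tuple(doc.get("families", FAMILIES)),
        factors=GridFactors(**fkw),
        **{k: int(v) for k, v in run_doc.items()},
    )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if doc is not None and not isinstance(doc, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(doc)


# ---------------------------------------------------------------------------
# tables


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack ScenarioSummary objects into one row-per-scenario DataFrame."""
    return pd.DataFrame([s.to_row() for s in summaries])


_METRICS = [
    ("c_derivation", "C-stat derivation"),
    ("c_validation", "C-stat validation"),
    ("slope", "Calibration slope"),
    ("citl", "Calibration-in-the-large (x10)"),
    ("brier_derivation", "Brier derivation"),
    ("brier_validation", "Brier validation"),
]


def _block_label(row) -> str:
    d, v = row["err_var_d0"], row["err_var_v0"]
    if d < v:
        return "noisier at validation"
    if d > v:
        return "more precise at validation"
    return "equal noise"


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.3f} ({sd:.3f})"


def render_single_predictor_table(frame: pd.DataFrame) -> str:
    """Pooled overview of the single-predictor grid.

    Rows are (noise-ordering block, psi_V, theta_V); each cell pools the
    (sigma_D, sigma_V) pairs in the block: mean over pairs of the per-pair
    summary, across-pair SD in parentheses.  CITL is shown x10.
    """
    sub = frame[frame["family"] == "single"].copy()
    if sub.empty:
        raise ValueError("no single-predictor scenarios in summary input")
    sub["block"] = sub.apply(_block_label, axis=1)
    lines = []
    header = ["block", "psi_V", "theta_V"] + [label for _, label in _METRICS]
    lines.append("\t".join(header))
    order = ["noisier at validation", "equal noise", "more precise at validation"]
    for block in order:
        blk = sub[sub["block"] == block]
        for (psi, theta), g in blk.groupby(["psi_v", "theta_v"], sort=True):
            cells = [block, f"{psi:g}", f"{theta:g}"]
            for key, _label in _METRICS:
                col = "slope_median" if key == "slope" else f"{key}_mean"
                vals = g[col].to_numpy(dtype=float)
                scale = 10.0 if key == "citl" else 1.0
                mean = vals.mean() * scale
                sd = (vals.std(ddof=1) if len(vals) > 1 else 0.0) * scale
                cells.append(_fmt(mean, sd))
            lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_differential_table(frame: pd.DataFrame) -> str:
    """Per-scenario table of the differential-error family (CITL x10)."""
    sub = frame[frame["family"].isin(["diff", "diffpreset"])].copy()
    if sub.empty:
        raise ValueError("no differential scenarios in summary input")
    lines = ["\t".join(["scenario_id"] + [label for _, label in _METRICS])]
    for _, row in sub.iterrows():
        cells = [str(row["scenario_id"])]
        for key, _label in _METRICS:
            col = "slope_median" if key == "slope" else f"{key}_mean"
            scale = 10.0 if key == "citl" else 1.0
            cells.append(_fmt(row[col] * scale, row[f"{key}_sd"] * scale))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# plots


def plot_calibration(
    y: np.ndarray,
    p: np.ndarray,
    slope: float | None = None,
    intercept: float | None = None,
    n_bins: int = 10,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Calibration plot: binned observed vs predicted risk, recalibration
    line, and a histogram of predicted probabilities along the bottom."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.special import expit, logit

    from .performance import calibration_curve, recalibrate

    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if slope is None or intercept is None:
        eps = 1e-12
        res = recalibrate(y, logit(np.clip(p, eps, 1 - eps)))
        slope, intercept = res.slope, res.intercept

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], ls=":", color="grey", label="ideal")
    grid = np.linspace(0.01, 0.99, 99)
    ax.plot(
        grid,
        expit(intercept + slope * np.log(grid / (1 - grid))),
        color="black",
        label=f"slope b = {slope:.2f}",
    )
    curve = calibration_curve(y, p, n_bins=n_bins)
    xs = [c[0] for c in curve]
    ys = [c[1] for c in curve]
    ax.plot(xs, ys, "o", color="tab:blue", label="binned observed")
    ax.hist(p, bins=40, weights=np.full(p.size, 0.15 / p.size) * 40, bottom=0.0,
            color="tab:grey", alpha=0.4)
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed proportion")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
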