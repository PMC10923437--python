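"""Replicate harness: simulate, estimate, and summarize estimator accuracy.

For each replicate a fresh cohort is simulated (replicate ``r`` uses seed
``base_seed + r``), each requested method is applied in both directions, and
accuracy is summarized per (method, direction) cell as:

* median of the estimates,
* MAB — median absolute bias, ``median(|estimate - truth|)``,
* RMAB — MAB / |truth|, undefined (None) when the true effect is 0,

together with the mean first-stage instrument F-statistic.  A replicate on
which one method fails still contributes to the other methods' summaries;
failure counts are reported, never silently dropped.
"""

from __future__ import annotations

import importlib.resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import BiMRError, BMRParameters, ReplicateSummary, ValidationError
from .liml import biliml, naive_liml
from .ratio import biratio, naive_bidirectional_ratio
from .regress import mean_instrument_f
from .simulate import ScenarioConfig, simulate_bmr, simulate_umr

__all__ = [
    "mab",
    "rmab",
    "run_benchmark",
    "render_results_table",
    "summaries_frame",
    "load_scenario_blocks",
    "packaged_scenario_path",
]

METHODS = ("ratio", "biratio", "liml", "biliml")

_ESTIMATORS = {
    "ratio": naive_bidirectional_ratio,
    "biratio": biratio,
    "liml": naive_liml,
    "biliml": biliml,
}


def mab(estimates: Sequence[float], truth: float) -> float:
    """Median absolute bias: median of |estimate - truth|."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise ValidationError("mab requires at least one estimate")
    return float(np.median(np.abs(arr - truth)))


def rmab(mab_value: float, truth: float) -> Optional[float]:
    """Relative median absolute bias MAB/|truth| (fraction); None when truth is 0."""
    if truth == 0.0:
        return None
    return float(mab_value / abs(truth))


def run_benchmark(
    config: ScenarioConfig,
    methods: Sequence[str] = METHODS,
    confounder_visible: bool = False,
) -> List[ReplicateSummary]:
    """Run ``config.n_reps`` replicates and summarize each method/direction.

    With ``confounder_visible`` the simulated confounder is handed to every
    estimator as an observed covariate; by default it stays unmeasured, which
    is the MR premise.
    """
    for m in methods:
        if m not in _ESTIMATORS:
            raise ValidationError(f"unknown method {m!r}; choose from {list(_ESTIMATORS)}")
    simulate = simulate_umr if config.kind == "umr" else simulate_bmr
    estimates: Dict[Tuple[str, str], List[float]] = {
        (m, d): [] for m in methods for d in ("1->2", "2->1")
    }
    failures: Dict[str, int] = {m: 0 for m in methods}
    f_sum = np.zeros(2)
    for r in range(config.n_reps):
        data = simulate(config, seed=config.seed + r)
        cov = data.confounder[:, None] if confounder_visible else None
        f_sum[0] += mean_instrument_f(data, 1)
        f_sum[1] += mean_instrument_f(data, 2)
        for m in methods:
            try:
                est12, est21 = _ESTIMATORS[m](data, covariates=cov)
            except BiMRError:
                failures[m] += 1
                continue
            estimates[(m, "1->2")].append(est12.estimate)
            estimates[(m, "2->1")].append(est21.estimate)
    mean_f = f_sum / config.n_reps
    truths = {"1->2": config.params.gamma12, "2->1": config.params.gamma21}
    label = config.label or config.kind
    summaries = []
    for m in methods:
        for i, d in enumerate(("1->2", "2->1")):
            ests = estimates[(m, d)]
            cell_mab = mab(ests, truths[d])
            summaries.append(
                ReplicateSummary(
                    scenario=label,
                    method=m,
                    direction=d,
                    true_value=truths[d],
                    median_estimate=float(np.median(ests)),
                    mab=cell_mab,
                    rmab=rmab(cell_mab, truths[d]),
                    mean_f=float(mean_f[i]),
                    n_reps=len(ests),
                    n_failed=failures[m],
                )
            )
    return summaries


def summaries_frame(summaries: Sequence[ReplicateSummary]) -> pd.DataFrame:
    """Benchmark summaries as a tidy DataFrame (one row per cell)."""
    if not summaries:
        raise ValidationError("no summaries to tabulate")
    return pd.DataFrame(
        {
            "scenario": [s.scenario for s in summaries],
            "method": [s.method for s in summaries],
            "direction": [s.direction for s in summaries],
            "true_value": [s.true_value for s in summaries],
            "mean_f": [s.mean_f for s in summaries],
            "median": [s.median_estimate for s in summaries],
            "mab": [s.mab for s in summaries],
            "rmab": [s.rmab for s in summaries],
            "n_reps": [s.n_reps for s in summaries],
            "n_failed": [s.n_failed for s in summaries],
        }
    )


def _fmt_rmab(value: Optional[float]) -> str:
    return "-" if value is None else f"{round(value * 100):d}%"


def render_results_table(summaries: Sequence[ReplicateSummary]) -> str:
    """Plain-text results table: one sub-row per direction, per-method
    Median/MAB/RMAB columns, two-decimal medians/MAB, integer-percent RMAB,
    '-' for undefined RMAB."""
    if not summaries:
        raise ValidationError("no summaries to render")
    frame = summaries_frame(summaries)
    methods = list(dict.fromkeys(frame["method"]))
    header = f"{'scenario':<24}{'truth':>8}{'F-stat':>10}"
    for m in methods:
        header += f"{m + ' med':>12}{'MAB':>7}{'RMAB':>7}"
    lines = [header, "-" * len(header)]
    for (scenario, direction), grp in frame.groupby(
        ["scenario", "direction"], sort=False
    ):
        row = grp.set_index("method")
        first = row.iloc[0]
        tag = "g12" if direction == "1->2" else "g21"
        line = (
            f"{scenario[:22] + ' ' + tag:<24}"
            f"{first['true_value']:>8.2f}{first['mean_f']:>10.2f}"
        )
        for m in methods:
            r = row.loc[m]
            line += f"{r['median']:>12.2f}{r['mab']:>7.2f}{_fmt_rmab(r['rmab']):>7}"
        lines.append(line)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Scenario configuration files (the full simulation-study grids)
# ---------------------------------------------------------------------------

_ALLOWED_TOP = {"kind", "n", "n_reps", "maf", "seed", "blocks"}
_ALLOWED_BLOCK = {"label", "n_instruments", "beta", "gammas", "strength"}


def packaged_scenario_path(name: str):
    """Path to a packaged scenario grid: 'scenario1', 'scenario2' or 'scenario3'."""
    res = importlib.resources.files("bimr") / "scenarios" / f"{name}.yaml"
    if not res.is_file():
        raise ValidationError(f"unknown packaged scenario {name!r}")
    return res


def load_scenario_blocks(source) -> List[ScenarioConfig]:
    """Parse a scenario grid file into one ScenarioConfig per (block, gamma pair).

    The file is a strict schema: top-level keys kind/n/n_reps/maf/seed/blocks;
    each block has label, n_instruments, beta (shared per-instrument effect),
    gammas (list of [gamma12, gamma21] pairs) and an optional strength label.
    Unknown keys are errors.
    """
    if hasattr(source, "read_text"):
        text = source.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValidationError("scenario file must be a mapping")
    unknown = set(doc) - _ALLOWED_TOP
    if unknown:
        raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("kind", "blocks"):
        if key not in doc:
            raise ValidationError(f"scenario file missing required key {key!r}")
    kind = doc["kind"]
    n = int(doc.get("n", 1000))
    n_reps = int(doc.get("n_reps", 1000))
    maf = float(doc.get("maf", 0.3))
    seed = int(doc.get("seed", 0))
    configs = []
    for block in doc["blocks"]:
        unknown = set(block) - _ALLOWED_BLOCK
        if unknown:
            raise ValidationError(f"unknown block keys: {sorted(unknown)}")
        for key in ("label", "n_instruments", "beta", "gammas"):
            if key not in block:
                raise ValidationError(f"scenario block missing required key {key!r}")
        k = int(block["n_instruments"])
        beta = float(block["beta"])
        for g12, g21 in block["gammas"]:
            params = BMRParameters(
                gamma12=float(g12),
                gamma21=float(g21),
                beta11=np.full(k, beta),
                beta22=np.full(k, beta),
                maf=maf,
                n=n,
            )
            configs.append(
                ScenarioConfig(
                    kind=kind,
                    params=params,
                    n_reps=n_reps,
                    seed=seed,
                    strength=block.get("strength"),
                    label=f"{block['label']} g12={g12} g21={g21}",
                )
            )
    return configs
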