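"""Batch comparison of constrained vs unconstrained overlap across networks.

The pipeline mirrors the two study designs the statistic was built for:

* groups of food webs compared with and without the trophic-level rule
  (group means of N̄ with 95% confidence intervals, and the paired
  constrained − unconstrained difference);
* collections of host–parasite worlds where N̄ is related to species
  diversity by Spearman rank correlation, under either specification of the
  shareable-partner parameter n.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import (
    reduction_report,
    task_match_permitted,
    trophic_levels,
    trophic_permitted,
    permitted_from_matrix,
)
from .errors import ParameterError
from .network import Network, PermittedInteractions, TraitTable
from .io import NetworkFileSpec, read_network, read_permitted_matrix, read_trait_table
from .overlap import mean_overlap

CONSTRAINTS = ("none", "trophic", "traits", "matrix", "given")


@dataclass
class BatchEntry:
    """One network to analyse: in-memory or on disk, plus its constraint."""

    id: str
    group: str = "all"
    network: Network | None = None
    file: NetworkFileSpec | None = None
    constraint: str = "none"
    traits: TraitTable | None = None
    traits_path: str | None = None
    matrix_path: str | None = None
    permitted: PermittedInteractions | None = None  # constraint="given"

    def load(self) -> Network:
        if self.network is not None:
            return self.network
        if self.file is None:
            raise ParameterError(f"entry {self.id!r} has neither a network nor a file")
        return read_network(self.file)


@dataclass(frozen=True)
class BatchRecord:
    """Per-network result of the constrained/unconstrained comparison."""

    id: str
    group: str
    n_species: int
    nbar_constrained: float
    nbar_unconstrained: float
    mean_reduction_ratio: float
    pairs_included_constrained: int
    pairs_included_unconstrained: int
    error: str | None = None

    @property
    def difference(self) -> float:
        return self.nbar_constrained - self.nbar_unconstrained

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "group": self.group,
            "n_species": self.n_species,
            "nbar_constrained": self.nbar_constrained,
            "nbar_unconstrained": self.nbar_unconstrained,
            "difference": self.difference,
            "mean_reduction_ratio": self.mean_reduction_ratio,
            "pairs_included_constrained": self.pairs_included_constrained,
            "pairs_included_unconstrained": self.pairs_included_unconstrained,
            "error": self.error,
        }


def _constraint_for(entry: BatchEntry, net: Network) -> PermittedInteractions:
    if entry.constraint == "none":
        return PermittedInteractions.fully_permissive(net)
    if entry.constraint == "trophic":
        return trophic_permitted(net, trophic_levels(net))
    if entry.constraint == "traits":
        traits = entry.traits
        if traits is None:
            if entry.traits_path is None:
                raise ParameterError(f"entry {entry.id!r}: traits constraint without traits")
            traits = read_trait_table(entry.traits_path)
        return task_match_permitted(net, traits)
    if entry.constraint == "matrix":
        if entry.matrix_path is None:
            raise ParameterError(f"entry {entry.id!r}: matrix constraint without matrix_path")
        return permitted_from_matrix(net, read_permitted_matrix(entry.matrix_path))
    if entry.constraint == "given":
        if entry.permitted is None:
            raise ParameterError(f"entry {entry.id!r}: constraint='given' without permitted")
        return entry.permitted
    raise ParameterError(f"entry {entry.id!r}: unknown constraint {entry.constraint!r}")


def batch_overlap(
    entries: Sequence[BatchEntry],
    scope: str | None = None,
    direction: str = "out",
    degenerate_policy: str = "exclude",
) -> list[BatchRecord]:
    """N̄ under the naive and the constrained n for every manifest entry.

    A failure on one network produces a record carrying the error message;
    the remaining entries still complete.
    """
    if not entries:
        raise ParameterError("empty manifest")
    records: list[BatchRecord] = []
    for entry in entries:
        try:
            net = entry.load()
            free = PermittedInteractions.fully_permissive(net)
            constrained = _constraint_for(entry, net)
            su = mean_overlap(net, free, scope=scope, direction=direction,
                              degenerate_policy=degenerate_policy, keep_pairs=False)
            sc = mean_overlap(net, constrained, scope=scope, direction=direction,
                              degenerate_policy=degenerate_policy, keep_pairs=False)
            eff_dir = direction if net.directed else "undirected"
            red = reduction_report(net, constrained, direction=eff_dir)
            records.append(
                BatchRecord(
                    id=entry.id,
                    group=entry.group,
                    n_species=net.n_nodes,
                    nbar_constrained=sc.mean_overlap,
                    nbar_unconstrained=su.mean_overlap,
                    mean_reduction_ratio=red.mean_ratio,
                    pairs_included_constrained=sc.n_pairs_included,
                    pairs_included_unconstrained=su.n_pairs_included,
                )
            )
        except Exception as exc:  # fault isolation across the manifest
            records.append(
                BatchRecord(
                    id=entry.id, group=entry.group, n_species=0,
                    nbar_constrained=math.nan, nbar_unconstrained=math.nan,
                    mean_reduction_ratio=math.nan,
                    pairs_included_constrained=0, pairs_included_unconstrained=0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return records


@dataclass(frozen=True)
class GroupSummary:
    """Mean N̄ ± 95% CI for one group of networks, plus the paired difference."""

    label: str
    which: str  # constrained | unconstrained
    n_networks: int
    mean_nbar: float
    ci95_halfwidth: float  # NaN when undefined (k < 2)
    mean_difference: float
    ci95_difference: float
    per_network: tuple[dict, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "which": self.which,
            "n_networks": self.n_networks,
            "mean_nbar": self.mean_nbar,
            "ci95_halfwidth": self.ci95_halfwidth,
            "mean_difference": self.mean_difference,
            "ci95_difference": self.ci95_difference,
        }


def _t_ci_halfwidth(values: np.ndarray) -> float:
    """t-based 95% CI halfwidth: t(0.975, k−1) · sd / √k; NaN for k < 2."""
    k = len(values)
    if k < 2:
        return math.nan
    sd = float(np.std(values, ddof=1))
    return float(stats.t.ppf(0.975, k - 1) * sd / math.sqrt(k))


def group_summary(
    records: Sequence[BatchRecord], label: str, which: str = "constrained"
) -> GroupSummary:
    """Summarize one group's N̄ values and paired differences.

    Records whose relevant N̄ is undefined (NaN) are left out of the mean;
    the CI is t-based and flagged undefined (NaN) for singleton groups.
    """
    group = [r for r in records if r.group == label and r.error is None]
    if not group:
        raise ParameterError(f"no usable record for group {label!r}")
    if which not in ("constrained", "unconstrained"):
        raise ParameterError(f"which must be constrained|unconstrained, got {which!r}")
    vals = np.array(
        [getattr(r, f"nbar_{which}") for r in group], dtype=float
    )
    vals = vals[~np.isnan(vals)]
    diffs = np.array([r.difference for r in group], dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if vals.size == 0:
        raise ParameterError(f"group {label!r}: no defined N̄ value")
    return GroupSummary(
        label=label,
        which=which,
        n_networks=len(group),
        mean_nbar=float(np.mean(vals)),
        ci95_halfwidth=_t_ci_halfwidth(vals),
        mean_difference=float(np.mean(diffs)) if diffs.size else math.nan,
        ci95_difference=_t_ci_halfwidth(diffs),
        per_network=tuple(r.to_dict() for r in group),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation of N̄ with species diversity."""

    rho: float
    p_value: float
    n: int
    method: str = "t-approximation"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n, "method": self.method}


def diversity_correlation(
    records: Sequence[BatchRecord],
    which: str = "constrained",
    method: str = "t",
) -> CorrelationResult:
    """Spearman's rho between species diversity and per-network N̄.

    Diversity is the total species count of the realized network (both guilds
    for bipartite webs).  Ties get average ranks.  ``method="t"`` uses the
    two-sided t-distribution approximation for the p-value; ``"permutation"``
    enumerates all rank permutations exactly (n ≤ 8 only — the count grows
    factorially).
    """
    if which not in ("constrained", "unconstrained"):
        raise ParameterError(f"which must be constrained|unconstrained, got {which!r}")
    pts = [
        (r.n_species, getattr(r, f"nbar_{which}"))
        for r in records
        if r.error is None and not math.isnan(getattr(r, f"nbar_{which}"))
    ]
    if len(pts) < 3:
        raise ParameterError("need at least 3 records with a defined N̄")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, math.nan, len(pts), method="undefined-zero-variance")
    if method == "t":
        res = stats.spearmanr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), len(pts))
    if method != "permutation":
        raise ParameterError(f"unknown method {method!r}")
    if len(pts) > 8:
        raise ParameterError("exact permutation p-value limited to n <= 8")
    rho = float(stats.spearmanr(x, y).statistic)
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    count = total = 0
    for perm in permutations(ry):
        r = float(np.corrcoef(rx, perm)[0, 1])
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return CorrelationResult(rho, count / total, len(pts), method="exact-permutation")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(
    out_dir: str | Path,
    records: Sequence[BatchRecord],
    summaries: Sequence[GroupSummary] = (),
    correlations: dict[str, CorrelationResult] | None = None,
    ratio_distributions: dict[str, Sequence[float]] | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Machine-readable CSV/JSON outputs plus optional summary plots.

    Writes ``records.csv`` (one row per network), ``summaries.csv`` (one row
    per group × metric variant), ``report.json`` (everything bundled), and —
    when ``plots`` is set — a boxplot of N̄ by group/constraint and density
    plots of per-node reduction ratios.  Plotting problems are reported as
    warnings, never raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rec_df = pd.DataFrame([r.to_dict() for r in records])
    paths["records"] = out / "records.csv"
    rec_df.to_csv(paths["records"], index=False)

    sum_df = pd.DataFrame([s.to_dict() for s in summaries])
    paths["summaries"] = out / "summaries.csv"
    sum_df.to_csv(paths["summaries"], index=False)

    bundle = {
        "records": [r.to_dict() for r in records],
        "group_summaries": [s.to_dict() for s in summaries],
        "correlations": {k: v.to_dict() for k, v in (correlations or {}).items()},
    }
    paths["json"] = out / "report.json"
    paths["json"].write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")

    if plots:
        try:
            paths.update(
                _plot_report(out, records, ratio_distributions or {})
            )
        except Exception as exc:  # plotting must never sink the pipeline
            import warnings

            warnings.warn(f"plotting skipped: {type(exc).__name__}: {exc}", stacklevel=2)
    return paths


def _plot_report(out: Path, records, ratio_distributions) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    groups = sorted({r.group for r in records if r.error is None})
    data, labels = [], []
    for g in groups:
        for which in ("unconstrained", "constrained"):
            vals = [
                getattr(r, f"nbar_{which}")
                for r in records
                if r.group == g and r.error is None
                and not math.isnan(getattr(r, f"nbar_{which}"))
            ]
            if vals:
                data.append(vals)
                labels.append(f"{g}\n{which[:7]}")
    if data:
        fig, ax = plt.subplots(figsize=(1.5 * len(data) + 2, 4))
        ax.boxplot(data, tick_labels=labels, whis=(0, 100), showfliers=True)
        ax.axhline(0.0, color="grey", lw=0.8, ls=":")
        ax.set_ylabel("mean standardized overlap $\\bar{N}$")
        fig.tight_layout()
        paths["boxplot"] = out / "nbar_boxplot.png"
        fig.savefig(paths["boxplot"], dpi=120)
        plt.close(fig)
    if ratio_distributions:
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, vals in sorted(ratio_distributions.items()):
            vals = np.asarray(list(vals), dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < 2 or np.std(vals) == 0:
                continue
            kde = stats.gaussian_kde(vals)
            xs = np.linspace(0, 1, 200)
            ax.plot(xs, kde(xs), label=label)
        ax.set_xlabel("reduced / complete potential-partner ratio")
        ax.set_ylabel("density")
        if ax.lines:
            ax.legend()
        fig.tight_layout()
        paths["density"] = out / "reduction_density.png"
        fig.savefig(paths["density"], dpi=120)
        plt.close(fig)
    return paths
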