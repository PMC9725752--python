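"""Stratification of per-mutation fitness tables by ICDC category.

Deep-mutational-scanning fitness values (or docking scores) are grouped by
the category of the mutated position, summarized, and compared pairwise
with the Mann-Whitney U test — a distribution-free choice, since mutational
fitness values are rarely normal.  A neutral band on the value scale
separates near-neutral substitutions from enhancing and deleterious ones;
the direction of "better" is configurable because relative fitness is
higher-is-better while docking energies are lower-is-better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enm import ResidueKey

log = logging.getLogger(__name__)

__all__ = [
    "read_fitness_table",
    "CategoryDistributions",
    "stratify",
    "compare_categories",
    "enhancing_fraction",
    "violin_plot",
]

REQUIRED_COLUMNS = ("position", "wt", "sub", "value")


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    """Read a per-mutation fitness CSV (position, wt, sub, value)."""
    table = pd.read_csv(path, comment="#")
    return validate_fitness_table(table)


def validate_fitness_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fitness table missing columns: {', '.join(missing)}")
    if table.duplicated(subset=["position", "sub"]).any():
        raise ValueError("duplicate (position, substitution) records in fitness table")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite fitness values")
    return table


@dataclass
class CategoryDistributions:
    """Per-category fitness values plus summary statistics."""

    values: dict[str, np.ndarray]
    summary: pd.DataFrame
    neutral_band: tuple[float, float]
    skipped_records: int = 0


def _summarize(values: np.ndarray, band: tuple[float, float]) -> dict[str, float]:
    lo, hi = band
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(med),
        "iqr": float(q3 - q1),
        "frac_above_band": float(np.mean(values > hi)),
        "frac_below_band": float(np.mean(values < lo)),
    }


def stratify(
    table: pd.DataFrame,
    icdc: pd.DataFrame,
    neutral_band: tuple[float, float] = (-0.1, 0.1),
    per_position_mean: bool = False,
) -> CategoryDistributions:
    """Group fitness records by their position's ICDC category.

    Records at binding-site, unclassified, or unknown positions are skipped
    with a logged count.  ``per_position_mean`` collapses each position to
    the mean over its substitutions before pooling.
    """
    validate_fitness_table(table)
    cat_of: dict[int, str] = {}
    for _, row in icdc.iterrows():
        cat_of[int(row["resnum"])] = row["category"]

    def resnum_of(pos) -> int:
        if isinstance(pos, str) and ":" in pos:
            return ResidueKey.parse(pos).number
        return int(pos)

    grouped: dict[str, list[float]] = {}
    skipped = 0
    work = table.copy()
    work["_resnum"] = [resnum_of(p) for p in work["position"]]
    if per_position_mean:
        work = work.groupby("_resnum", as_index=False).agg({"value": "mean"})
    for _, row in work.iterrows():
        cat = cat_of.get(int(row["_resnum"]))
        if cat is None or cat == "unclassified":
            skipped += 1
            continue
        grouped.setdefault(cat, []).append(float(row["value"]))
    if skipped:
        log.info("%d record(s) skipped (binding-site, unclassified or unknown positions)", skipped)
    if not grouped:
        raise ValueError("no fitness records at classified positions")
    values = {cat: np.asarray(v, dtype=float) for cat, v in sorted(grouped.items())}
    summary = pd.DataFrame(
        [{"category": cat, **_summarize(v, neutral_band)} for cat, v in values.items()]
    )
    return CategoryDistributions(
        values=values, summary=summary, neutral_band=neutral_band, skipped_records=skipped
    )


def compare_categories(
    dist: CategoryDistributions,
    pair: tuple[str, str],
    statistic: str = "value",
) -> dict[str, float]:
    """Two-sided Mann-Whitney U between two categories.

    ``statistic="abs_deviation"`` compares absolute deviations from the
    neutral-band midpoint (a dispersion contrast: two-tailed effects widen a
    distribution without shifting its center).  Exact enumeration is used
    for group sizes up to 20, the tie-corrected normal approximation above.
    Effect size is the rank-biserial correlation 2U/(n1 n2) - 1.
    """
    a, b = pair
    for cat in pair:
        if cat not in dist.values:
            raise KeyError(f"category {cat} not present in distributions")
    x, y = dist.values[a], dist.values[b]
    if x.size < 2 or y.size < 2:
        raise ValueError("both categories need at least 2 records")
    if statistic == "abs_deviation":
        mid = 0.5 * (dist.neutral_band[0] + dist.neutral_band[1])
        x, y = np.abs(x - mid), np.abs(y - mid)
    elif statistic != "value":
        raise ValueError("statistic must be 'value' or 'abs_deviation'")
    method = "exact" if max(x.size, y.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    effect = 2.0 * u / (x.size * y.size) - 1.0
    return {"statistic": u, "p_value": min(1.0, float(res.pvalue)), "effect": effect}


def enhancing_fraction(
    dist: CategoryDistributions,
    category: str,
    neutral_hi: float | None = None,
    direction: str = "higher",
) -> float:
    """Fraction of a category's records strictly better than the neutral edge.

    ``direction="higher"`` counts values above ``neutral_hi`` (fitness
    convention); ``direction="lower"`` counts values below it (docking-score
    convention, where ``neutral_hi`` is the low edge of the band).
    """
    if category not in dist.values:
        raise KeyError(f"category {category} not present in distributions")
    values = dist.values[category]
    if neutral_hi is None:
        neutral_hi = dist.neutral_band[1] if direction == "higher" else dist.neutral_band[0]
    if direction == "higher":
        return float(np.mean(values > neutral_hi))
    if direction == "lower":
        return float(np.mean(values < neutral_hi))
    raise ValueError("direction must be 'higher' or 'lower'")


def violin_plot(dist: CategoryDistributions, path: str | Path) -> None:
    """Render per-category violin plots to a file (optional reporting aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(dist.values)
    fig, ax = plt.subplots(figsize=(1.8 * len(cats) + 1, 4))
    ax.violinplot([dist.values[c] for c in cats], showmedians=True)
    ax.axhspan(*dist.neutral_band, color="0.85", zorder=0)
    ax.set_xticks(range(1, len(cats) + 1), cats)
    ax.set_ylabel("fitness value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
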