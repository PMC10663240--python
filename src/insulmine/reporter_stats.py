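"""Dual-reporter (GFP / mCherry) assay statistics.

A candidate insulator sits between a constitutively driven mCherry cassette
and a GFP cassette; insulator activity attenuates GFP. Per replicate the
GFP:mCherry ratio is formed, constructs are summarised by the mean ratio,
and each construct's fold change (FC) versus the minimal 21-bp spacer
control is

    FC = (ratio_construct - ratio_control) / ratio_control

so FC = 0 means no effect and FC = -0.845 means GFP reduced to 15.5 % of
the control. Group separation uses one-way ANOVA followed by all-pairs
Tukey HSD, summarised as a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

DEFAULT_CONTROL = "spacer21"


@dataclass(frozen=True)
class FluorescenceRecord:
    construct_id: str
    replicate: int
    gfp: float
    mcherry: float

    def __post_init__(self) -> None:
        if self.gfp < 0 or self.mcherry < 0:
            raise ValueError(
                f"{self.construct_id} rep {self.replicate}: fluorescence must be >= 0"
            )


@dataclass(frozen=True)
class AssayResult:
    construct_id: str
    n: int
    mean_ratio: float
    sd_ratio: float
    fc: float
    group_letter: str


def read_assay(path: str | Path) -> pd.DataFrame:
    """Read a plate TSV with columns construct_id, replicate, gfp, mcherry."""
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
    needed = {"construct_id", "replicate", "gfp", "mcherry"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: assay table must have columns {sorted(needed)}")
    return df


def ratios(records: pd.DataFrame | Sequence[FluorescenceRecord]) -> pd.DataFrame:
    """Per-replicate GFP/mCherry ratios.

    Replicates with mcherry == 0 are excluded with a warning; a construct
    with no usable replicate is an error. Returns a tidy frame with columns
    construct_id, replicate, ratio.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [
                {
                    "construct_id": r.construct_id,
                    "replicate": r.replicate,
                    "gfp": r.gfp,
                    "mcherry": r.mcherry,
                }
                for r in records
            ]
        )
    constructs = list(dict.fromkeys(records["construct_id"]))
    bad = records["mcherry"] == 0
    for r in records[bad].itertuples(index=False):
        logger.warning(
            "construct %s replicate %s: mcherry = 0, replicate excluded",
            r.construct_id,
            r.replicate,
        )
    usable = records[~bad].copy()
    empty = set(constructs) - set(usable["construct_id"])
    if empty:
        raise ValueError(f"constructs with no usable replicates: {sorted(empty)}")
    usable["ratio"] = usable["gfp"] / usable["mcherry"]
    return usable[["construct_id", "replicate", "ratio"]].reset_index(drop=True)


def fold_change_vs_control(mean_ratio: float, control_mean_ratio: float) -> float:
    """FC of a construct's mean ratio against the spacer control's."""
    if control_mean_ratio <= 0:
        raise ValueError(f"control mean ratio must be > 0, got {control_mean_ratio}")
    return (mean_ratio - control_mean_ratio) / control_mean_ratio


def compare_groups(ratio_table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA plus Tukey-HSD compact letter display over constructs.

    Returns the ANOVA F and p, the Tukey result, and a construct -> letters
    mapping in which two constructs share no letter iff their pairwise
    comparison is significant at ``alpha``.
    """
    groups = {cid: g["ratio"].to_numpy() for cid, g in ratio_table.groupby("construct_id")}
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least 2 constructs")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("compare_groups needs >= 2 replicates per construct")
    # zero within-group variance (noiseless synthetic data) divides by zero
    # inside the studentized range; the resulting inf statistics are correct
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p_value = stats.f_oneway(*groups.values())
        tukey = pairwise_tukeyhsd(
            endog=ratio_table["ratio"].to_numpy(),
            groups=ratio_table["construct_id"].to_numpy(),
            alpha=alpha,
        )
    names = list(tukey.groupsunique)
    significant: set[frozenset[str]] = set()
    for (i, j), reject in zip(
        ((i, j) for i in range(len(names)) for j in range(i + 1, len(names))),
        tukey.reject,
    ):
        if reject:
            significant.add(frozenset((names[i], names[j])))
    means = {cid: float(np.mean(v)) for cid, v in groups.items()}
    letters = compact_letter_display(sorted(groups, key=lambda c: -means[c]), significant)
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "tukey": tukey,
        "letters": letters,
    }


def compact_letter_display(
    ordered_groups: Sequence[str], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts with a single letter spanning all groups; every significant pair
    splits each letter set containing both; subset letter sets are absorbed.
    Group order (by descending mean) fixes which letters come first, making
    the labelling deterministic.
    """
    sets: list[set[str]] = [set(ordered_groups)]
    for pair in sorted(significant_pairs, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            sets.extend((s - {a}, s - {b}))
        sets = [s for s in sets if s and not any(s < t for t in sets)]
        # drop duplicates while keeping order
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    # order letters by the best-ranked group they contain
    rank = {g: i for i, g in enumerate(ordered_groups)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in ordered_groups}
    for letter, s in zip(alphabet, sets):
        for g in ordered_groups:
            if g in s:
                out[g] += letter
    return out


def summarize_assay(
    records: pd.DataFrame,
    control: str = DEFAULT_CONTROL,
    alpha: float = 0.05,
) -> list[AssayResult]:
    """Full per-construct summary: n, mean ratio, SD, FC vs control, letter."""
    table = ratios(records)
    if control not in set(table["construct_id"]):
        raise ValueError(f"control construct {control!r} absent from assay table")
    comparison = compare_groups(table, alpha=alpha) if table["construct_id"].nunique() > 1 else {
        "letters": {c: "a" for c in table["construct_id"].unique()}
    }
    summary = table.groupby("construct_id")["ratio"].agg(["count", "mean", "std"])
    control_mean = float(summary.loc[control, "mean"])
    results = []
    for cid, row in summary.iterrows():
        results.append(
            AssayResult(
                construct_id=str(cid),
                n=int(row["count"]),
                mean_ratio=float(row["mean"]),
                sd_ratio=float(row["std"]) if row["count"] > 1 else 0.0,
                fc=fold_change_vs_control(float(row["mean"]), control_mean),
                group_letter=comparison["letters"].get(str(cid), ""),
            )
        )
    return sorted(results, key=lambda r: r.construct_id)


def results_to_frame(results: Sequence[AssayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": r.construct_id,
                "n": r.n,
                "mean_ratio_gfp_over_mcherry": r.mean_ratio,
                "sd_ratio": r.sd_ratio,
                "fc_vs_control": r.fc,
                "group_letter": r.group_letter,
            }
            for r in results
        ]
    )
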